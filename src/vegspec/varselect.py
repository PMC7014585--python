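"""Permutation-importance ranking and forward selection of covariates.

Covariates are first ranked by permutation importance on a large ranking
forest (default ntree=2000, mtry=p/2): each covariate's values are permuted
across samples once and the resulting increase in out-of-bag error over the
unpermuted baseline is its importance.  The ranked list is then traversed
once in a forward selection — a covariate is retained iff adding it strictly
increases OOB accuracy of a fresh (default-configured) forest over the
current set.  Intended for data that need no per-tree downsampling (e.g.
hand-held spectroscopy samples); downsampling makes rankings unstable across
repeat runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import FittedForest, ForestConfig, balanced_forest_fit, oob_accuracy
from .features import CovariateTable
from .spectra import SpectraError

logger = logging.getLogger(__name__)


@dataclass
class ImportanceRanking:
    """Permutation importance (OOB error increase) per covariate."""

    importances: dict[str, float]
    order: list[str]  # descending importance; ties keep column order

    def rank(self, name: str) -> int:
        return self.order.index(name) + 1


@dataclass
class SelectionResult:
    """Outcome of the forward selection."""

    selected: list[str]
    trajectory: pd.DataFrame  # columns: step, covariate, oob_accuracy, accepted
    ranking: ImportanceRanking
    config: dict = field(default_factory=dict)

    def save(self, path) -> None:
        self.trajectory.to_csv(path, index=False)


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, CovariateTable):
        return table.table
    if isinstance(table, pd.DataFrame):
        return table
    arr = np.asarray(table, dtype=float)
    return pd.DataFrame(arr, columns=[f"x{i}" for i in range(arr.shape[1])])


def permutation_importance(model: FittedForest, table, labels,
                           seed: int = 0) -> ImportanceRanking:
    """OOB permutation importance of every covariate of a fitted forest.

    For covariate j, its column is permuted across all samples (one draw per
    seed) and each tree re-predicts its OOB samples on the permuted matrix;
    importance_j = permuted OOB error - baseline OOB error.  Constant
    covariates get importance 0 by definition.
    """
    df = _as_frame(table)
    X = df[model.feature_names].to_numpy(dtype=float)
    y = np.asarray(labels)
    baseline = 1.0 - oob_accuracy(model)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    importances: dict[str, float] = {}
    class_index = {c: i for i, c in enumerate(model.classes_)}
    y_codes = np.array([class_index[v] for v in y])
    for j, name in enumerate(model.feature_names):
        col = X[:, j]
        if np.all(col == col[0]):
            importances[name] = 0.0
            logger.info("covariate %s is constant; importance 0", name)
            rng.permutation(n)  # keep the seed stream aligned across covariates
            continue
        perm = rng.permutation(n)
        Xp = X.copy()
        Xp[:, j] = col[perm]
        votes = np.zeros((n, model.n_classes), dtype=int)
        for tree, oob in zip(model.trees, model.oob_masks):
            if not oob.any():
                continue
            pred = tree.predict(Xp[oob]).astype(int)
            np.add.at(votes, (np.nonzero(oob)[0], pred), 1)
        has = votes.sum(axis=1) > 0
        err = float(np.mean(np.argmax(votes[has], axis=1) != y_codes[has]))
        importances[name] = err - baseline
    order = sorted(model.feature_names,
                   key=lambda c: (-importances[c], model.feature_names.index(c)))
    return ImportanceRanking(importances, order)


def forward_select(
    table,
    labels,
    ranking_config: ForestConfig | None = None,
    selection_config: ForestConfig | None = None,
    seed: int = 0,
    min_improvement: float = 0.0,
) -> SelectionResult:
    """Rank covariates by permutation importance, then forward-select.

    The ranking forest defaults to ntree=2000 and mtry=p/2; the selection
    forests default to ordinary settings (mtry=sqrt(p)).  The ranked list is
    traversed once; a candidate is retained iff OOB accuracy rises by more
    than ``min_improvement`` (strict improvement at the default 0).
    """
    df = _as_frame(table)
    y = np.asarray(labels)
    p = df.shape[1]
    if p < 1:
        raise SpectraError("forward selection needs at least 1 covariate")
    if ranking_config is None:
        ranking_config = ForestConfig(ntree=2000, mtry=max(1, p // 2),
                                      seed=seed)
    if selection_config is None:
        selection_config = ForestConfig(seed=seed)

    ranking_model = balanced_forest_fit(df, y, ranking_config)
    ranking = permutation_importance(ranking_model, df, y, seed=seed)

    selected: list[str] = []
    best_acc = -np.inf
    rows = []
    for step, name in enumerate(ranking.order, start=1):
        candidate = selected + [name]
        cfg = ForestConfig(ntree=selection_config.ntree,
                           mtry=min(selection_config.mtry or
                                    max(1, int(np.sqrt(len(candidate)))),
                                    len(candidate)),
                           downsample_target=selection_config.downsample_target,
                           seed=np.random.SeedSequence([seed, step]).generate_state(1)[0] % (2**31))
        model = balanced_forest_fit(df[candidate], y, cfg)
        acc = oob_accuracy(model)
        # the top-ranked covariate always starts the set
        accepted = (not selected) or acc > best_acc + min_improvement
        if accepted:
            selected = candidate
            best_acc = acc
        rows.append({"step": step, "covariate": name,
                     "oob_accuracy": acc, "accepted": accepted})
    trajectory = pd.DataFrame(rows)
    return SelectionResult(
        selected=selected,
        trajectory=trajectory,
        ranking=ranking,
        config={"ranking": vars(ranking_config), "selection": vars(selection_config),
                "seed": seed, "min_improvement": min_improvement},
    )
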