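"""Class-balanced random-forest classification with geographic validation.

Vegetation ground truth is heavily imbalanced: common communities contribute
thousands of pixels, rare ones a few hundred.  An ordinary bootstrap then
trades minority-class error for majority-class error.  Here each tree in the
ensemble draws a *capped* bootstrap: at most ``downsample_target`` samples
per category (with replacement within category), so every tree sees a more
balanced training set while out-of-bag (OOB) bookkeeping still covers all
samples.

Validation honours spatial structure: patches of each vegetation type are
split geographically into two contiguous halves (training / validation), and
accuracy is measured on repeated random draws of validation pixels capped per
category, summarised over repeats.  Agreement is reported as overall accuracy
and Cohen's kappa computed from the confusion matrix:

    kappa = (N * sum_i x_ii - sum_i x_i+ * x_+i) / (N^2 - sum_i x_i+ * x_+i)

with x_ii the diagonal counts, x_i+/x_+i the row/column sums and N the total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .features import CovariateTable
from .spectra import SpectralDataset, SpectraError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# confusion matrix + agreement metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    """Square count matrix; rows are reference, columns are prediction."""

    categories: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        object.__setattr__(self, "counts", c)
        r = len(self.categories)
        if c.shape != (r, r):
            raise SpectraError("confusion matrix must be square over categories")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise SpectraError("confusion counts must be nonnegative integers")
        if c.sum() == 0:
            raise SpectraError("empty confusion matrix")

    @classmethod
    def from_labels(cls, reference, predicted,
                    categories: Sequence[str] | None = None) -> "ConfusionMatrix":
        ref = np.asarray(reference)
        pred = np.asarray(predicted)
        if ref.shape != pred.shape:
            raise SpectraError("reference/prediction length mismatch")
        if categories is None:
            categories = sorted(set(ref) | set(pred))
        categories = tuple(str(c) for c in categories)
        lut = {c: i for i, c in enumerate(categories)}
        counts = np.zeros((len(categories), len(categories)), dtype=int)
        np.add.at(counts,
                  ([lut[str(r)] for r in ref], [lut[str(p)] for p in pred]), 1)
        return cls(categories, counts)

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.categories),
                            columns=list(self.categories))


def accuracy(cm: ConfusionMatrix) -> float:
    """Overall accuracy: correctly classified count over total count."""
    return float(np.trace(cm.counts) / cm.n_total)


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa — chance-corrected agreement of the confusion matrix.

    Returns NaN when the chance-agreement term saturates (denominator zero),
    i.e. when all mass sits in a single row/column pair.
    """
    counts = cm.counts.astype(float)
    n = counts.sum()
    diag = np.trace(counts)
    chance = float(counts.sum(axis=1) @ counts.sum(axis=0))
    denom = n * n - chance
    if denom == 0:
        logger.warning("kappa undefined: chance agreement saturates")
        return float("nan")
    return float((n * diag - chance) / denom)


# ---------------------------------------------------------------------------
# balanced forest
# ---------------------------------------------------------------------------

@dataclass
class ForestConfig:
    """Tuning for the balanced ensemble.

    ``mtry`` (covariates tried per split) defaults to floor(sqrt(p));
    ``downsample_target`` caps the per-category bootstrap draw of every tree
    (None disables capping).  2000 trees give stable accuracies for real
    analyses; tests use far fewer.
    """

    ntree: int = 200
    mtry: int | None = None
    downsample_target: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise SpectraError("ntree must be >= 1")
        if self.downsample_target is not None and self.downsample_target < 1:
            raise SpectraError("downsample_target must be >= 1")


#: full-scale per-category caps per experiment condition
DOWNSAMPLE_PRESETS = {
    "nvc_wide": 1000,
    "dom_species_wide": 1500,
    "narrow": 300,
}


class FittedForest:
    """A fitted balanced ensemble with OOB vote bookkeeping."""

    def __init__(self, trees, classes, oob_votes, oob_masks, feature_names,
                 config: ForestConfig):
        self.trees = trees
        self.classes_ = classes
        self.oob_votes = oob_votes            # (n_samples, n_classes) counts
        self.oob_masks = oob_masks            # (ntree, n_samples) bool, True = OOB
        self.feature_names = list(feature_names)
        self.config = config

    @property
    def n_classes(self) -> int:
        return len(self.classes_)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Majority vote over trees; ties go to the first class in sorted order."""
        X = np.asarray(X, dtype=float)
        votes = np.zeros((X.shape[0], self.n_classes), dtype=int)
        for tree in self.trees:
            pred = tree.predict(X).astype(int)
            np.add.at(votes, (np.arange(X.shape[0]), pred), 1)
        return self.classes_[np.argmax(votes, axis=1)]

    def predict_table(self, table: CovariateTable) -> np.ndarray:
        return self.predict(table.table[self.feature_names].to_numpy(dtype=float))

    def oob_predictions(self) -> tuple[np.ndarray, np.ndarray]:
        """(majority OOB label per sample, mask of samples with >= 1 OOB vote)."""
        has_votes = self.oob_votes.sum(axis=1) > 0
        pred = self.classes_[np.argmax(self.oob_votes, axis=1)]
        return pred, has_votes


def _capped_bootstrap(y_codes: np.ndarray, cap: int | None,
                      rng: np.random.Generator) -> np.ndarray:
    """Per-category bootstrap indices: at most ``cap`` draws per category."""
    draws = []
    for c in np.unique(y_codes):
        idx = np.nonzero(y_codes == c)[0]
        k = idx.size if cap is None else min(idx.size, cap)
        draws.append(rng.choice(idx, size=k, replace=True))
    return np.concatenate(draws)


def balanced_forest_fit(table: CovariateTable | pd.DataFrame | np.ndarray,
                        labels, config: ForestConfig) -> FittedForest:
    """Fit the class-balanced ensemble.

    Every tree trains on a per-category capped bootstrap (categories below
    the cap contribute a same-size bootstrap of their own samples); samples
    outside a tree's draw are that tree's OOB set.  The underlying tree
    learner is a CART classifier with ``mtry`` features tried per split.
    """
    if isinstance(table, CovariateTable):
        X = table.values()
        feature_names = table.columns
    elif isinstance(table, pd.DataFrame):
        X = table.to_numpy(dtype=float)
        feature_names = list(table.columns)
    else:
        X = np.asarray(table, dtype=float)
        feature_names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise SpectraError("covariate rows != label count")
    if not np.all(np.isfinite(X)):
        raise SpectraError("covariate table contains non-finite values")
    classes, y_codes = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise SpectraError("need at least two categories")

    sizes = np.bincount(y_codes)
    cap = config.downsample_target
    if cap is not None and cap >= sizes.max():
        logger.warning("downsample_target %d >= largest category (%d): no-op cap",
                       cap, sizes.max())
    p = X.shape[1]
    mtry = config.mtry if config.mtry is not None else max(1, int(np.sqrt(p)))
    if not 1 <= mtry <= p:
        raise SpectraError(f"mtry {mtry} outside [1, {p}]")

    rng = np.random.default_rng(config.seed)
    n = X.shape[0]
    trees = []
    oob_votes = np.zeros((n, classes.size), dtype=int)
    oob_masks = np.zeros((config.ntree, n), dtype=bool)
    for t in range(config.ntree):
        draw = _capped_bootstrap(y_codes, cap, rng)
        tree = DecisionTreeClassifier(
            max_features=mtry, random_state=int(rng.integers(2**31)))
        tree.fit(X[draw], y_codes[draw])
        oob = np.ones(n, dtype=bool)
        oob[draw] = False
        oob_masks[t] = oob
        if oob.any():
            pred = tree.predict(X[oob]).astype(int)
            np.add.at(oob_votes, (np.nonzero(oob)[0], pred), 1)
        trees.append(tree)
    model = FittedForest(trees, classes, oob_votes, oob_masks, feature_names, config)
    model._y_ref = y
    return model


def oob_accuracy(model: FittedForest, labels=None) -> float:
    """Fraction of samples whose OOB majority vote matches the reference.

    Uses the labels stored at fit time unless ``labels`` overrides them;
    samples never out of bag are excluded (and logged).
    """
    pred, has_votes = model.oob_predictions()
    y = model._y_ref if labels is None else np.asarray(labels)
    if (~has_votes).any():
        logger.info("oob_accuracy: %d samples with no OOB votes excluded",
                    int((~has_votes).sum()))
    if not has_votes.any():
        raise SpectraError("no sample has OOB votes")
    return float(np.mean(pred[has_votes] == y[has_votes]))


def per_class_oob_error(model: FittedForest) -> dict[str, float]:
    """Per-category OOB error rate (1 - recall of the OOB majority vote)."""
    pred, has_votes = model.oob_predictions()
    y = model._y_ref
    out = {}
    for c in model.classes_:
        m = has_votes & (y == c)
        out[str(c)] = float(np.mean(pred[m] != y[m])) if m.any() else float("nan")
    return out


# ---------------------------------------------------------------------------
# geographic split
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Training/validation assignment from the geographic two-half split."""

    train_patches: dict[str, set]
    val_patches: dict[str, set]
    assignment: pd.Series           # sample_id -> 'train' | 'val' | 'excluded'
    excluded_types: list[str] = field(default_factory=list)

    def train_mask(self, dataset: SpectralDataset) -> np.ndarray:
        return (self.assignment.reindex(dataset.sample_ids) == "train").to_numpy()

    def val_mask(self, dataset: SpectralDataset) -> np.ndarray:
        return (self.assignment.reindex(dataset.sample_ids) == "val").to_numpy()


def _principal_axis(points: np.ndarray) -> np.ndarray:
    """First principal axis of 2-D points, oriented towards +x (ties +y)."""
    centred = points - points.mean(axis=0)
    cov = centred.T @ centred
    eigvals, eigvecs = np.linalg.eigh(cov)
    axis = eigvecs[:, int(np.argmax(eigvals))]
    if axis[0] < 0 or (axis[0] == 0 and axis[1] < 0):
        axis = -axis
    return axis


def _two_half_split(keys: list, points: np.ndarray) -> tuple[set, set]:
    """Split units at the median of their principal-axis projection.

    The half containing the westernmost unit (minimum x, ties minimum y)
    becomes training.  Degenerate layouts (all projections equal) fall back
    to an even split of the deterministic ordering.
    """
    proj = points @ _principal_axis(points)
    median = np.median(proj)
    lower = proj <= median
    if lower.all() or not lower.any():
        order = np.lexsort((points[:, 1], points[:, 0]))
        lower = np.zeros(len(keys), dtype=bool)
        lower[order[: len(keys) // 2]] = True
    west = int(np.lexsort((points[:, 1], points[:, 0]))[0])
    train_side = lower if lower[west] else ~lower
    train = {keys[i] for i in np.nonzero(train_side)[0]}
    val = {keys[i] for i in np.nonzero(~train_side)[0]}
    return train, val


def geographic_split(dataset: SpectralDataset, by: str = "type_id") -> SplitPlan:
    """Split every vegetation type's patches geographically into two halves.

    Patch centroids are projected onto the first principal axis of their
    layout and cut at the median; the westernmost half trains.  Types with a
    single patch are split the same way at the pixel level; types with fewer
    than two samples are excluded.
    """
    meta = dataset.meta
    for col in (by, "patch_id", "x", "y"):
        if col not in meta.columns:
            raise SpectraError(f"geographic split needs metadata column {col!r}")
    assignment = pd.Series("excluded", index=pd.Index(dataset.sample_ids,
                                                      name="sample_id"))
    train_patches: dict[str, set] = {}
    val_patches: dict[str, set] = {}
    excluded: list[str] = []
    for type_id, group in meta.groupby(by, sort=True):
        if len(group) < 2:
            excluded.append(str(type_id))
            logger.info("type %s excluded from split (<2 samples)", type_id)
            continue
        patches = group.groupby("patch_id")[["x", "y"]].mean()
        if len(patches) >= 2:
            train, val = _two_half_split(
                list(patches.index), patches.to_numpy(dtype=float))
            train_patches[str(type_id)] = train
            val_patches[str(type_id)] = val
            sel_train = group["patch_id"].isin(train)
            assignment.loc[group.loc[sel_train, "sample_id"]] = "train"
            assignment.loc[group.loc[~sel_train, "sample_id"]] = "val"
        else:
            # single patch: apply the same rule to its pixels
            ids = list(group["sample_id"])
            train, val = _two_half_split(ids, group[["x", "y"]].to_numpy(float))
            patch = str(group["patch_id"].iloc[0])
            train_patches[str(type_id)] = {patch}
            val_patches[str(type_id)] = set()
            assignment.loc[list(train)] = "train"
            assignment.loc[list(val)] = "val"
    return SplitPlan(train_patches, val_patches, assignment, excluded)


# ---------------------------------------------------------------------------
# repeated capped validation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationResult:
    """Accuracy/kappa per validation repeat plus a mean/min/max summary."""

    repeats: list[tuple[float, float, ConfusionMatrix]]
    summary: dict[str, float]

    @property
    def accuracies(self) -> list[float]:
        return [a for a, _, _ in self.repeats]

    @property
    def kappas(self) -> list[float]:
        return [k for _, k, _ in self.repeats]


def evaluate(model: FittedForest, table: CovariateTable | pd.DataFrame,
             labels, downsample_target: int | None,
             repeats: int = 5, seed: int = 0) -> EvaluationResult:
    """Repeated capped validation of a fitted model.

    Per repeat, up to ``downsample_target`` validation samples per category
    are drawn without replacement, predicted, and scored (accuracy, kappa).
    Categories absent from a repeat's draw are dropped from that matrix.
    The caller is responsible for validation samples being disjoint from
    training (use :func:`geographic_split`).
    """
    df = table.table if isinstance(table, CovariateTable) else table
    X = df[model.feature_names].to_numpy(dtype=float)
    y = np.asarray(labels).astype(str)
    results = []
    for rep in range(repeats):
        rng = np.random.default_rng([seed, rep])
        sel = []
        for c in np.unique(y):
            idx = np.nonzero(y == c)[0]
            k = idx.size if downsample_target is None else min(idx.size,
                                                               downsample_target)
            if k == 0:
                logger.info("repeat %d: category %s empty, dropped", rep, c)
                continue
            sel.append(rng.choice(idx, size=k, replace=False))
        sel = np.concatenate(sel)
        pred = model.predict(X[sel]).astype(str)
        cm = ConfusionMatrix.from_labels(y[sel], pred)
        results.append((accuracy(cm), kappa(cm), cm))
    accs = [a for a, _, _ in results]
    kaps = [k for _, k, _ in results]
    summary = {
        "accuracy_mean": float(np.mean(accs)),
        "accuracy_min": float(np.min(accs)),
        "accuracy_max": float(np.max(accs)),
        "kappa_mean": float(np.nanmean(kaps)),
        "kappa_min": float(np.nanmin(kaps)),
        "kappa_max": float(np.nanmax(kaps)),
    }
    return EvaluationResult(results, summary)
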