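"""Dominant-species vegetation categorisation from percent-cover tables.

Plots (4 m^2 sample areas) are characterised by the percent cover of their
three most abundant plant species and grouped by unsupervised random-forest
clustering: a same-shape reference table is synthesised by independently
permuting each species column, a forest is trained to tell observed from
reference rows, the fraction of trees in which two observed plots share a
terminal node defines their proximity p_ij, and partitioning around medoids
(PAM) on the dissimilarity d_ij = sqrt(1 - p_ij) yields cluster labels at
each requested cluster count — one count per thematic resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .spectra import SpectraError

logger = logging.getLogger(__name__)

#: the four thematic-resolution cluster counts used for wide-patch data in
#: the motivating field campaign (finest to coarsest)
RESOLUTION_PRESET_WIDE = (17, 9, 7, 4)


def load_cover_table(path) -> pd.DataFrame:
    """Read a long-format cover table (sample_id, species, percent_cover)."""
    df = pd.read_csv(path)
    required = {"sample_id", "species", "percent_cover"}
    if not required <= set(df.columns):
        raise SpectraError(f"cover table needs columns {sorted(required)}")
    wide = df.pivot_table(index="sample_id", columns="species",
                          values="percent_cover", fill_value=0.0, aggfunc="sum")
    return validate_cover_table(wide)


def save_cover_table(table: pd.DataFrame, path) -> None:
    long = table.reset_index().melt(id_vars="sample_id", var_name="species",
                                    value_name="percent_cover")
    long = long[long["percent_cover"] > 0]
    long.to_csv(path, index=False)


def validate_cover_table(table: pd.DataFrame) -> pd.DataFrame:
    vals = table.to_numpy(dtype=float)
    if vals.min() < 0 or vals.max() > 100:
        raise SpectraError("percent covers must lie in [0, 100]")
    return table


def top3_cover(table: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Keep each plot's ``k`` most abundant species; zero the rest.

    Ties at rank ``k`` are resolved alphabetically by species name.  Species
    retained by no plot are dropped from the result's columns.
    """
    validate_cover_table(table)
    out = table.copy().astype(float)
    for sid, row in table.iterrows():
        nonzero = row[row > 0]
        if nonzero.empty:
            raise SpectraError(f"plot {sid!r} has no species cover")
        # sort by descending cover, then species name ascending
        ranked = nonzero.sort_index().sort_values(ascending=False,
                                                  kind="stable")
        keep = set(ranked.index[:k])
        out.loc[sid, [s for s in table.columns if s not in keep]] = 0.0
    kept = out.columns[(out > 0).any(axis=0)]
    return out[kept]


def permuted_reference(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Reference table with every column independently permuted.

    Column marginals match the observed table exactly; the joint structure
    between species is destroyed, which is what the discriminating forest
    learns to detect.
    """
    return np.column_stack([rng.permutation(X[:, j]) for j in range(X.shape[1])])


@dataclass
class ClusterSolution:
    """Plot-to-cluster labels at each requested thematic resolution."""

    labels: dict[int, pd.Series]      # cluster count -> sample_id -> label (1-based)
    proximity: pd.DataFrame           # observed-plot proximity matrix
    medoids: dict[int, list]          # cluster count -> medoid sample_ids

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({f"k{k}": s for k, s in self.labels.items()})


def _pam(d: np.ndarray, k: int, rng: np.random.Generator,
         max_iter: int = 100) -> tuple[np.ndarray, list[int]]:
    """Partitioning around medoids (classic BUILD + SWAP) on a dissimilarity matrix."""
    n = d.shape[0]
    # BUILD: greedy medoid initialisation
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        current = d[:, medoids].min(axis=1)
        gains = np.array([
            np.maximum(current - d[:, j], 0).sum() if j not in medoids else -np.inf
            for j in range(n)])
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)
    # SWAP until no single medoid/non-medoid exchange lowers total cost
    def cost(meds):
        return d[:, meds].min(axis=1).sum()
    best = cost(medoids)
    for _ in range(max_iter):
        improved = False
        for mi in range(k):
            for j in range(n):
                if j in medoids:
                    continue
                trial = sorted(medoids[:mi] + [j] + medoids[mi + 1:])
                c = cost(trial)
                if c < best - 1e-12:
                    medoids, best, improved = trial, c, True
        if not improved:
            break
    assign = np.argmin(d[:, medoids], axis=1)
    return assign, medoids


def proximity_cluster(
    table: pd.DataFrame,
    cluster_counts: list[int],
    ntree: int = 500,
    seed: int = 0,
) -> ClusterSolution:
    """Unsupervised-forest clustering of a (top-3) cover table.

    See the module docstring for the permuted-reference / proximity / PAM
    chain.  Cluster labels are 1-based and contiguous at every level;
    requested counts must be below the plot count.
    """
    validate_cover_table(table)
    X = table.to_numpy(dtype=float)
    n = X.shape[0]
    for k in cluster_counts:
        if k >= n:
            raise SpectraError(f"cluster count {k} >= sample count {n}")
        if k < 1:
            raise SpectraError("cluster counts must be >= 1")
    rng = np.random.default_rng(seed)
    reference = permuted_reference(X, rng)
    Xy = np.vstack([X, reference])
    y = np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])
    forest = RandomForestClassifier(n_estimators=ntree,
                                    random_state=int(rng.integers(2**31)))
    forest.fit(Xy, y)

    leaves = forest.apply(X)  # (n, ntree) terminal-node ids of observed plots
    prox = np.zeros((n, n))
    for t in range(leaves.shape[1]):
        same = leaves[:, t, None] == leaves[None, :, t]
        prox += same
    prox /= leaves.shape[1]
    d = np.sqrt(np.maximum(1.0 - prox, 0.0))
    np.fill_diagonal(d, 0.0)

    labels: dict[int, pd.Series] = {}
    medoids: dict[int, list] = {}
    for k in sorted(set(cluster_counts), reverse=True):
        assign, meds = _pam(d, k, rng)
        # contiguous 1-based labels (degenerate data can leave medoids unused)
        remap = {u: i + 1 for i, u in enumerate(np.unique(assign))}
        labels[k] = pd.Series([remap[a] for a in assign], index=table.index,
                              name=f"k{k}")
        medoids[k] = [table.index[m] for m in meds]
    prox_df = pd.DataFrame(prox, index=table.index, columns=table.index)
    return ClusterSolution(labels=labels, proximity=prox_df, medoids=medoids)
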