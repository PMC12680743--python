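"""Biosynthetic-group assignment: PCA, k-means and completeness thresholds.

Genomes stratify into three biosynthetic completeness groups.  Two routes
are provided and should agree on well-separated data:

* printed thresholds on the per-genome average completeness:
  Low = [0, 0.30), Medium = [0.30, 0.625), High = [0.625, 1];
* k-means (k = 3) on the first five principal components of the
  (mean-centered, unscaled) completeness matrix, with clusters relabeled by
  ascending mean completeness so cluster 1 is always the lowest group.

The High group can be further split into two subclusters (k = 2 in the same
PC space), which in the source data separates, e.g., the main B12 producers
from the rest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "PCAResult",
    "pca",
    "kmeans_groups",
    "assign_threshold_group",
    "biosynthetic_groups",
    "split_high_group",
    "LOW_MEDIUM_BOUNDARY",
    "MEDIUM_HIGH_BOUNDARY",
]

LOW_MEDIUM_BOUNDARY = 0.30
MEDIUM_HIGH_BOUNDARY = 0.625
GROUP_ORDER = ("Low", "Medium", "High")


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame            # genomes × PCs
    loadings: pd.DataFrame          # modules × PCs
    explained_variance_ratio: np.ndarray


def pca(matrix: pd.DataFrame, n_components: int = 5) -> PCAResult:
    """PCA of the completeness matrix: columns mean-centered, not scaled
    (all modules already live on the common [0, 1] scale).

    Components are ordered by decreasing explained variance with a
    deterministic sign convention (the largest-magnitude loading of each
    component is positive).  Requesting more components than the matrix rank
    truncates with a warning.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 genomes and 2 modules")
    x = matrix.to_numpy(float)
    rank = np.linalg.matrix_rank(x - x.mean(axis=0))
    if n_components > rank:
        warnings.warn(f"n_components={n_components} exceeds rank {rank}; truncating")
        n_components = max(1, rank)
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x)
    loadings = model.components_.T  # modules × PCs
    # sign convention: largest-|loading| entry of each PC is positive
    for j in range(loadings.shape[1]):
        pivot = np.argmax(np.abs(loadings[:, j]))
        if loadings[pivot, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    pcs = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=pcs),
        loadings=pd.DataFrame(loadings, index=matrix.columns, columns=pcs),
        explained_variance_ratio=model.explained_variance_ratio_,
    )


def kmeans_groups(pc_scores: pd.DataFrame, avg_all: pd.Series, k: int = 3,
                  seed: int = 1, n_restarts: int = 10) -> pd.Series:
    """Seeded best-of-restarts k-means on PC scores.

    Labels are relabeled 1..k by ascending cluster mean of ``avg_all``, so
    cluster 1 is the lowest-completeness cluster regardless of the
    initialization.
    """
    if len(pc_scores) < k:
        raise ValueError(f"need at least {k} points for k={k}")
    model = KMeans(n_clusters=k, n_init=n_restarts,
                   random_state=np.random.RandomState(seed))
    raw = model.fit_predict(pc_scores.to_numpy(float))
    means = pd.Series(avg_all.loc[pc_scores.index].to_numpy(),
                      index=raw).groupby(level=0).mean()
    order = means.sort_values(kind="stable").index
    relabel = {old: new + 1 for new, old in enumerate(order)}
    return pd.Series([relabel[r] for r in raw], index=pc_scores.index,
                     name="kmeans_cluster")


def assign_threshold_group(avg_all: float) -> str:
    """Threshold group for one average-completeness value in [0, 1].

    Half-open intervals, boundaries assigned upward: Low = [0, 0.30),
    Medium = [0.30, 0.625), High = [0.625, 1].
    """
    if not 0.0 <= avg_all <= 1.0:
        raise ValueError(f"average completeness {avg_all} outside [0, 1]")
    if avg_all < LOW_MEDIUM_BOUNDARY:
        return "Low"
    if avg_all < MEDIUM_HIGH_BOUNDARY:
        return "Medium"
    return "High"


def biosynthetic_groups(matrix: pd.DataFrame, avg_all: pd.Series,
                        k: int = 3, n_components: int = 5, seed: int = 1,
                        n_restarts: int = 10) -> pd.DataFrame:
    """Full grouping table: threshold group, k-means cluster and PC scores."""
    res = pca(matrix, n_components=n_components)
    clusters = kmeans_groups(res.scores, avg_all, k=k, seed=seed,
                             n_restarts=n_restarts)
    out = pd.DataFrame({
        "avg_all": avg_all.loc[matrix.index],
        "group": [assign_threshold_group(v) for v in avg_all.loc[matrix.index]],
        "kmeans_cluster": clusters,
    }, index=matrix.index)
    return pd.concat([out, res.scores], axis=1)


def split_high_group(groups: pd.DataFrame, seed: int = 1,
                     n_restarts: int = 10) -> pd.Series:
    """k-means (k = 2) subcluster split of the High threshold group in the
    already-computed PC space; labels "A" (larger mean avg_all) and "B"."""
    high = groups[groups["group"] == "High"]
    if len(high) < 2:
        raise ValueError("High group has fewer than 2 members")
    pc_cols = [c for c in groups.columns if c.startswith("PC")]
    sub = kmeans_groups(high[pc_cols], high["avg_all"], k=2, seed=seed,
                        n_restarts=n_restarts)
    return sub.map({2: "A", 1: "B"}).rename("high_subcluster")
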