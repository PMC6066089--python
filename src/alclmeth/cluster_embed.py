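"""Sample-relatedness analyses: normalization, probe selection, hierarchical
clustering, PCA and nearest-reference-stage assignment.

Two conventions coexist deliberately: heatmap-style clustering runs on raw β
(percent-methylation scale), while PCA / reference-stage comparisons first
z-score each sample to mean 0 and variance 1 to remove per-array intensity
offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core_io import BetaMatrix, SampleSheet, ValidationError, REFERENCE_PREFIX


def zscore_samples(df: pd.DataFrame) -> pd.DataFrame:
    """Center each sample column to mean 0 and population variance 1."""
    vals = df.to_numpy(dtype=float)
    mu = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = list(df.columns[sd == 0])
        raise ValidationError(f"zero-variance sample column(s): {bad}")
    return pd.DataFrame((vals - mu) / sd, index=df.index, columns=df.columns)


def select_top_probes(stat_table: pd.DataFrame, fraction: float | None = None,
                      p_max: float | None = None) -> list[str]:
    """Top probes by ascending p; ties by larger |Δβ|, then probe_id.

    Exactly one of ``fraction`` (ceil(fraction × total) probes) or ``p_max``
    (all probes with p < p_max) must be given.
    """
    if (fraction is None) == (p_max is None):
        raise ValueError("give exactly one of fraction or p_max")
    tab = stat_table.assign(_absd=stat_table["delta_beta"].abs(),
                            _pid=stat_table.index.astype(str))
    tab = tab.sort_values(["p", "_absd", "_pid"], ascending=[True, False, True])
    if fraction is not None:
        k = math.ceil(fraction * len(stat_table))
        return list(tab.index[:k])
    return list(tab.index[tab["p"] < p_max])


@dataclass
class Dendrogram:
    """Agglomerative clustering result on samples."""

    sample_ids: list[str]
    linkage: np.ndarray  # scipy linkage matrix
    metric: str
    method: str

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        return [self.sample_ids[i] for i in hierarchy.leaves_list(self.linkage)]

    def labels(self, k: int) -> dict[str, int]:
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.sample_ids, (int(x) for x in flat)))

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.sample_ids[node.id]
            d_l = node.dist - node.left.dist
            d_r = node.dist - node.right.dist
            return f"({rec(node.left)}:{d_l:.6f},{rec(node.right)}:{d_r:.6f})"

        return rec(tree) + ";"


def correlation_distance(df: pd.DataFrame) -> np.ndarray:
    """1 − Pearson correlation between sample columns (condensed form)."""
    vals = df.to_numpy(dtype=float)
    if np.any(vals.std(axis=0) == 0):
        raise ValidationError("correlation metric undefined for constant sample column")
    d = 1.0 - np.corrcoef(vals.T)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return squareform(d, checks=False)


def hier_cluster(df: pd.DataFrame, metric: str = "correlation",
                 method: str = "average") -> Dendrogram:
    """Hierarchical clustering of the sample columns.

    Default distance is 1 − Pearson correlation with average linkage.
    ``metric="euclidean"`` is also supported.
    """
    if df.shape[1] < 2:
        raise ValidationError("need >= 2 samples to cluster")
    if metric == "correlation":
        cond = correlation_distance(df)
    elif metric == "euclidean":
        from scipy.spatial.distance import pdist

        cond = pdist(df.to_numpy(dtype=float).T)
    else:
        raise ValueError(f"unsupported metric: {metric}")
    Z = hierarchy.linkage(cond, method=method)
    return Dendrogram(list(df.columns), Z, metric, method)


@dataclass
class EmbeddingResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples × components
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    components: np.ndarray  # components × probes (loadings)
    mean: np.ndarray

    def reconstruct(self) -> np.ndarray:
        """Samples × probes reconstruction from the retained components."""
        return self.coordinates @ self.components + self.mean


def pca(df: pd.DataFrame, n_components: int | None = None) -> EmbeddingResult:
    """PCA of samples (columns) in probe space via SVD.

    Sign convention: each component's largest-magnitude loading is positive,
    so coordinates are invariant to sample reordering up to row permutation.
    """
    X = df.to_numpy(dtype=float).T  # samples × probes
    n_samples, n_probes = X.shape
    max_comp = min(n_samples, n_probes)
    k = max_comp if n_components is None else min(n_components, max_comp)
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # fix signs
    for i in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    ev = S ** 2 / max(n_samples - 1, 1)
    total = ev.sum()
    ratio = ev / total if total > 0 else np.zeros_like(ev)
    return EmbeddingResult(
        sample_ids=list(df.columns),
        coordinates=(U * S)[:, :k],
        explained_variance=ev[:k],
        explained_variance_ratio=ratio[:k],
        components=Vt[:k],
        mean=mean,
    )


def stage_centroids(reference: pd.DataFrame, sheet: SampleSheet) -> pd.DataFrame:
    """Mean profile per REFERENCE_STAGE group (probes × stages)."""
    stages: dict[str, list[str]] = {}
    for s in reference.columns:
        g = sheet.group_of(s)
        if not g.startswith(REFERENCE_PREFIX):
            raise ValidationError(f"sample {s} is not a reference stage sample")
        stages.setdefault(g[len(REFERENCE_PREFIX):], []).append(s)
    return pd.DataFrame({st: reference[cols].mean(axis=1) for st, cols in stages.items()})


def assign_nearest_stage(tumor: pd.DataFrame, reference: pd.DataFrame,
                         sheet: SampleSheet) -> pd.DataFrame:
    """Assign each tumor sample to the reference stage with the nearest centroid.

    Euclidean distance over the (shared, usually normalized) probe rows; ties
    resolve to the first stage in input order and are flagged. Returns a
    samples × stages distance table plus ``assigned_stage`` and ``tie``.
    """
    cents = stage_centroids(reference, sheet)
    if not tumor.index.equals(cents.index):
        cents = cents.loc[tumor.index]
    dist = pd.DataFrame(
        {
            st: np.sqrt(((tumor.to_numpy() - cents[st].to_numpy()[:, None]) ** 2).sum(axis=0))
            for st in cents.columns
        },
        index=tumor.columns,
    )
    vals = dist.to_numpy()
    best = vals.argmin(axis=1)
    tie = (vals == vals[np.arange(len(best)), best][:, None]).sum(axis=1) > 1
    dist["assigned_stage"] = [dist.columns[i] for i in best]
    dist["tie"] = tie
    return dist
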