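"""Correlation-distance hierarchical clustering of genes (or samples).

The gene-module discovery step: pairwise distance d = 1 - Pearson r,
agglomeration by average linkage (UPGMA, inter-cluster distance = the
unweighted mean of all cross-cluster pairwise distances), and a cut of the
dendrogram into k clusters by removing the k-1 highest merges. Clustering
samples instead of genes is the same code path on the transposed matrix.

Neither the distance metric nor the linkage is sacred — they are the
defaults of the classic two-way clustering framework for expression data —
so both are arguments throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .matrix import ExpressionMatrix


class ClusterError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray  # square, symmetric, zero diagonal

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ClusterError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.all(np.isfinite(self.d)):
            raise ClusterError("non-finite distances")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ClusterError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ClusterError("nonzero diagonal in distance matrix")
        if (self.d < -1e-12).any():
            raise ClusterError("negative distances")


@dataclass
class Dendrogram:
    """Agglomeration result: scipy-format merge table plus leaf ids.

    ``merges`` is the (n-1) x 4 linkage array: merged node indices (leaves
    0..n-1, then internal nodes n, n+1, ...), merge height, new cluster
    size. Average linkage cannot invert, so heights are checked to be
    non-decreasing on construction.
    """

    merges: np.ndarray
    leaf_ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if self.merges.shape != (n - 1, 4):
            raise ClusterError(
                f"expected {n - 1} merges for {n} leaves, got {self.merges.shape[0]}"
            )
        heights = self.merges[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ClusterError("merge heights decrease: inverted dendrogram")

    def to_newick(self) -> str:
        """Newick string with merge heights as branch lengths."""
        n = len(self.leaf_ids)
        height = {i: 0.0 for i in range(n)}

        def node(i: int) -> str:
            if i < n:
                return self.leaf_ids[i]
            left, right, h, _ = self.merges[i - n]
            parts = []
            for child in (int(left), int(right)):
                parts.append(f"{node(child)}:{h - height[child]:.10g}")
            height[i] = h
            return "(" + ",".join(parts) + ")"

        for i in range(n - 1):
            height[n + i] = self.merges[i, 2]
        return node(2 * n - 2) + ";"


def correlation_distance(
    matrix: ExpressionMatrix, axis: str = "genes"
) -> DistanceMatrix:
    """Pairwise d = 1 - Pearson r over genes (rows) or samples (columns)."""
    if axis not in ("genes", "samples"):
        raise ClusterError(f"axis must be 'genes' or 'samples', got {axis!r}")
    vals = matrix.values if axis == "genes" else matrix.values.T
    if vals.shape[0] < 2:
        raise ClusterError(f"need at least 2 {axis} to cluster")
    if vals.shape[1] < 3:
        raise ClusterError(f"need at least 3 observations per item, got {vals.shape[1]}")
    sd = vals.std(axis=1, ddof=0)
    flat = list(vals.index[sd == 0])
    if flat:
        raise ClusterError(
            f"zero-variance {axis} make correlation distance undefined: {flat}"
        )
    r = np.corrcoef(vals.values)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)  # symmetrize away rounding
    return DistanceMatrix(ids=list(vals.index), d=d)


#: linkage rules that are monotone on a distance matrix alone
LINKAGE_METHODS = ("average", "complete", "single")


def linkage_tree(dist: DistanceMatrix, method: str = "average") -> Dendrogram:
    """Agglomerate a validated distance matrix with the given linkage rule."""
    if method not in LINKAGE_METHODS:
        raise ClusterError(
            f"unsupported linkage {method!r}; choose from {LINKAGE_METHODS}"
        )
    merges = hierarchy.linkage(squareform(dist.d, checks=False), method=method)
    return Dendrogram(merges=merges, leaf_ids=list(dist.ids))


def average_linkage(dist: DistanceMatrix) -> Dendrogram:
    """UPGMA agglomeration of a validated distance matrix."""
    return linkage_tree(dist, "average")


@dataclass
class GeneClusterPartition:
    """Item id -> cluster label. For k=2 the labels are upper/lower when an
    orientation matrix is supplied, otherwise c1/c2 in merge order."""

    labels: pd.Series
    k: int

    def members(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    @property
    def sizes(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()


def cut_k_clusters(
    dendro: Dendrogram,
    k: int = 2,
    matrix: ExpressionMatrix | None = None,
    reference_samples=None,
) -> GeneClusterPartition:
    """Cut the dendrogram into k clusters (remove the k-1 highest merges).

    For k=2, when ``matrix`` and ``reference_samples`` are given, the
    cluster with the higher mean expression over the reference samples is
    labelled ``upper`` and the other ``lower`` — a display convention
    matching heatmap orientation, with no effect on membership.
    """
    n = len(dendro.leaf_ids)
    if not (1 <= k <= n):
        raise ClusterError(f"k={k} out of range [1, {n}]")
    flat = hierarchy.fcluster(dendro.merges, t=k, criterion="maxclust")
    labels = pd.Series(
        [f"c{c}" for c in flat], index=dendro.leaf_ids, dtype=object
    )
    if k == 2 and matrix is not None and reference_samples is not None:
        ref = matrix.subset_samples(list(reference_samples)).values
        means = {
            lab: float(ref.loc[labels.index[labels == lab]].values.mean())
            for lab in labels.unique()
        }
        upper = max(means, key=lambda lab: means[lab])
        labels = labels.map(lambda lab: "upper" if lab == upper else "lower")
    if k >= 2 and labels.nunique() < 2:
        raise ClusterError("cut produced a single cluster; degenerate dendrogram")
    return GeneClusterPartition(labels=labels, k=k)
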