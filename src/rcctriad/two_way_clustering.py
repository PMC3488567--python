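"""Agglomerative machinery: Euclidean distances, average linkage (UPGMA),
tree cutting, cophenetic distances, and paired gene/sample clusterings.

Samples and genes are clustered with unweighted average linkage on Euclidean
distances, the combination classically used for two-way heatmap displays of
log-intensity microarray data.  No row/column standardization is applied by
default; the values are clustered as-is on the log2 scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform

from .io_core import ExpressionMatrix


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances over named items."""

    item_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.item_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("distance matrix shape does not match item count")
        if not np.isfinite(self.matrix).all():
            raise ValueError("non-finite distances")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")

    @property
    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)


@dataclass
class Dendrogram:
    """Agglomeration result: scipy-format linkage over named leaves.

    ``linkage`` has n-1 rows (left, right, height, size) in scipy's cluster
    numbering (leaves 0..n-1, merges n..2n-2).
    """

    item_ids: list[str]
    linkage: np.ndarray

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    @property
    def merges(self) -> list[tuple[int, int, float]]:
        return [(int(l), int(r), float(h)) for l, r, h, _ in self.linkage]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        order = sch.leaves_list(self.linkage)
        return [self.item_ids[i] for i in order]

    def cophenetic(self) -> DistanceMatrix:
        coph = squareform(sch.cophenet(self.linkage))
        return DistanceMatrix(self.item_ids, coph)

    def subtree_leaves(self) -> dict[int, list[int]]:
        """Leaf indices under every internal node, keyed by scipy node id."""
        n = self.n_items
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        for k, (left, right, _, _) in enumerate(self.linkage):
            members[n + k] = members[int(left)] + members[int(right)]
        return {node: leaves for node, leaves in members.items() if node >= n}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage, columns=["left", "right", "height", "size"]
        )


@dataclass
class TwoWayClustering:
    """Paired gene and sample dendrograms over one gene set."""

    gene_dendrogram: Dendrogram
    sample_dendrogram: Dendrogram
    gene_set_name: str = ""


def euclidean_distances(matrix: ExpressionMatrix, axis: str) -> DistanceMatrix:
    """Pairwise Euclidean distances between samples or between genes."""
    if axis == "samples":
        data = matrix.values
        ids = matrix.sample_ids
    elif axis == "genes":
        data = matrix.values.T
        ids = matrix.gene_ids
    else:
        raise ValueError(f"axis must be 'samples' or 'genes', got {axis!r}")
    if not np.isfinite(data).all():
        raise ValueError("non-finite values in expression matrix")
    return DistanceMatrix(ids, squareform(pdist(data, metric="euclidean")))


def average_linkage(dist: DistanceMatrix) -> Dendrogram:
    """UPGMA: merge the closest pair of clusters; the distance from a merged
    cluster to any other is the size-weighted mean of its parts' distances."""
    if len(dist.item_ids) < 2:
        raise ValueError("need at least 2 items to cluster")
    linkage = sch.linkage(dist.condensed, method="average")
    return Dendrogram(list(dist.item_ids), linkage)


def cut_tree(dendrogram: Dendrogram, k: int) -> pd.Series:
    """Partition the leaves into exactly k clusters by undoing the k-1
    highest (latest) merges.  Returns a Series item_id -> cluster index."""
    n = dendrogram.n_items
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    labels = sch.cut_tree(dendrogram.linkage, n_clusters=k).ravel()
    return pd.Series(labels, index=dendrogram.item_ids, name="cluster")


def two_way_cluster(
    matrix: ExpressionMatrix, gene_subset, gene_set_name: str = ""
) -> TwoWayClustering:
    """Cluster genes (distances across all samples) and samples (distances
    across the gene subset only) for one gene set."""
    gene_subset = [g for g in gene_subset if g in matrix.data.columns]
    if len(gene_subset) < 2:
        raise ValueError("gene_subset must contain at least 2 matrix genes")
    sub = matrix.subset_genes(gene_subset)
    gene_dend = average_linkage(euclidean_distances(sub, "genes"))
    sample_dend = average_linkage(euclidean_distances(sub, "samples"))
    return TwoWayClustering(gene_dend, sample_dend, gene_set_name)


def write_dendrogram(dendrogram: Dendrogram, path) -> None:
    df = dendrogram.to_frame()
    df.insert(0, "merge", range(len(df)))
    df.to_csv(path, sep="\t", index=False)


def write_partition(partition: pd.Series, path) -> None:
    out = partition.rename("cluster").to_frame()
    out.index.name = "id"
    out.to_csv(path, sep="\t")
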