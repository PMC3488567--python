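"""Two-stage pathway-anchored sample grouping.

Stage one clusters each sufficiently large gene set two-ways and selects up
to a handful of gene clusters (subtrees of the gene dendrogram) whose
induced sample clustering best reproduces the overall array clustering —
an explicit, reproducible stand-in for picking the "most representative"
heatmap blocks by eye.  Stage two pools the selected genes across sets and
re-clusters all samples on that union, cutting the tree into the tumor
groups A/B/C (plus a cell-line group when cell lines are present).

A stability analysis re-clusters the samples on several random gene subsets
and scores agreement with the final assignment by the adjusted Rand index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .io_core import ExpressionMatrix, GeneSetCollection, SampleAnnotation
from .io_core import filter_absent_probes, filter_by_set_size
from .two_way_clustering import (
    TwoWayClustering,
    average_linkage,
    cut_tree,
    euclidean_distances,
    two_way_cluster,
)

logger = logging.getLogger(__name__)

TUMOR_LABELS = ("A", "B", "C")
CELL_LINE = "CELL_LINE"


@dataclass
class GroupingParams:
    """Tunables of the grouping pipeline.

    ``min_set_size`` follows the observation that only gene sets well above
    ~150 members produce clearly distinguishable gene clusters (20 is the
    permissive exploratory threshold).  ``k_groups`` is 4 when cell lines
    are in the cohort (A/B/C + cell lines) and 3 tumor-only.
    """

    min_set_size: int = 150
    max_clusters_per_set: int = 4
    min_cluster_genes: int = 5
    k_groups: int = 4
    n_random_sets: int = 5
    random_set_size: int = 660
    max_subtree_fraction: float = 0.8
    seed: int = 0
    label_override: dict[int, str] | None = None

    def __post_init__(self) -> None:
        if self.k_groups < 2:
            raise ValueError("k_groups must be >= 2")
        for name in ("min_set_size", "min_cluster_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.max_clusters_per_set < 0 or self.n_random_sets < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class GroupAssignment:
    """Final per-sample labels plus the signature genes that produced them."""

    labels: pd.Series  # sample_id -> label
    signature_genes: list[str]
    provenance: dict = field(default_factory=dict)

    def tumor_labels(self) -> pd.Series:
        return self.labels[self.labels != CELL_LINE]


@dataclass
class SelectedCluster:
    """A gene-dendrogram subtree chosen as representative, with its score."""

    genes: list[str]
    score: float
    gene_set_name: str = ""


def adjusted_rand_index(p1: pd.Series, p2: pd.Series) -> float:
    """Chance-corrected agreement between two partitions of the same items."""
    if set(p1.index) != set(p2.index):
        raise ValueError("partitions are over different item sets")
    p2 = p2.loc[p1.index]
    return float(adjusted_rand_score(p1.to_numpy(), p2.to_numpy()))


def _cluster_samples_on_genes(
    matrix: ExpressionMatrix, genes, k: int
) -> pd.Series:
    sub = matrix.subset_genes(genes)
    dend = average_linkage(euclidean_distances(sub, "samples"))
    return cut_tree(dend, k)


def reference_partition(matrix: ExpressionMatrix, params: GroupingParams) -> pd.Series:
    """Overall array clustering: all genes, samples cut at k_groups."""
    return _cluster_samples_on_genes(matrix, matrix.gene_ids, params.k_groups)


def select_representative_clusters(
    twoway: TwoWayClustering,
    matrix: ExpressionMatrix,
    reference: pd.Series,
    params: GroupingParams,
) -> list[SelectedCluster]:
    """Score every eligible gene-tree subtree by how well a sample clustering
    restricted to its genes reproduces ``reference`` (adjusted Rand index);
    return up to ``max_clusters_per_set`` disjoint subtrees with positive
    score, greedily by descending score."""
    if params.max_clusters_per_set == 0:
        return []
    gene_dend = twoway.gene_dendrogram
    n_set = gene_dend.n_items
    max_size = int(params.max_subtree_fraction * n_set)
    candidates: list[SelectedCluster] = []
    for node, leaf_idx in gene_dend.subtree_leaves().items():
        if not params.min_cluster_genes <= len(leaf_idx) <= max_size:
            continue
        genes = [gene_dend.item_ids[i] for i in leaf_idx]
        part = _cluster_samples_on_genes(matrix, genes, params.k_groups)
        score = adjusted_rand_index(part, reference)
        if score > 0:
            candidates.append(SelectedCluster(genes, score, twoway.gene_set_name))
    candidates.sort(key=lambda c: (-c.score, len(c.genes)))

    selected: list[SelectedCluster] = []
    used: set[str] = set()
    for cand in candidates:
        if used.intersection(cand.genes):
            continue
        selected.append(cand)
        used.update(cand.genes)
        if len(selected) >= params.max_clusters_per_set:
            break
    return selected


def _map_cluster_labels(
    sample_dend,
    partition: pd.Series,
    params: GroupingParams,
    annotation: SampleAnnotation | None,
) -> pd.Series:
    """Name the cut clusters.

    The cluster dominated by cell-line samples (when annotation is given and
    k allows one) is the cell-line group.  Among tumor clusters, B is the
    one most distant from the others in mean cophenetic distance and, of
    the remaining two, A is the internally tighter cluster — both measured
    on ``sample_dend``, which should be built genome-wide (B's distinctness
    and A's tightness are genome-wide observations, not properties of the
    pooled signature alone).  An explicit override map wins over the
    heuristic.
    """
    cluster_ids = sorted(partition.unique())
    if params.label_override:
        mapping = dict(params.label_override)
        missing = [c for c in cluster_ids if c not in mapping]
        if missing:
            raise ValueError(f"label_override missing clusters {missing}")
        return partition.map(mapping)

    coph = sample_dend.cophenetic().matrix
    idx_of = {s: i for i, s in enumerate(sample_dend.item_ids)}
    members = {
        c: [idx_of[s] for s in partition.index[partition == c]] for c in cluster_ids
    }

    mapping: dict[int, str] = {}
    tumor_clusters = list(cluster_ids)
    if annotation is not None and len(cluster_ids) > len(TUMOR_LABELS):
        cl_frac = {
            c: (
                annotation.loc(partition.index[partition == c])["sample_class"]
                == "cell_line"
            ).mean()
            for c in cluster_ids
        }
        cell_cluster = max(cl_frac, key=cl_frac.get)
        mapping[cell_cluster] = CELL_LINE
        tumor_clusters.remove(cell_cluster)

    def between(c1: int, c2: int) -> float:
        return float(coph[np.ix_(members[c1], members[c2])].mean())

    def within(c: int) -> float:
        idx = members[c]
        if len(idx) < 2:
            return 0.0
        sub = coph[np.ix_(idx, idx)]
        return float(sub[np.triu_indices(len(idx), 1)].mean())

    remaining = list(tumor_clusters)
    labels_left = list(TUMOR_LABELS[: len(remaining)])
    if len(remaining) >= 2 and "B" in labels_left:
        sep = {
            c: np.mean([between(c, o) for o in remaining if o != c]) for c in remaining
        }
        b_cluster = max(sep, key=sep.get)
        mapping[b_cluster] = "B"
        remaining.remove(b_cluster)
        labels_left.remove("B")
    if len(remaining) == 2 and labels_left == ["A", "C"]:
        tightness = {c: within(c) for c in remaining}
        a_cluster = min(tightness, key=tightness.get)
        mapping[a_cluster] = "A"
        remaining.remove(a_cluster)
        mapping[remaining[0]] = "C"
    else:  # degenerate k: assign whatever labels are left in order
        for c, lab in zip(remaining, labels_left):
            mapping[c] = lab
    return partition.map(mapping)


def combine_and_recluster(
    matrix: ExpressionMatrix,
    selected_clusters: list[SelectedCluster],
    params: GroupingParams,
    annotation: SampleAnnotation | None = None,
) -> GroupAssignment:
    """Pool selected genes across sets, re-cluster all samples on the union,
    cut at k_groups and name the clusters."""
    union: list[str] = []
    seen: set[str] = set()
    for cluster in selected_clusters:
        for g in cluster.genes:
            if g not in seen:
                union.append(g)
                seen.add(g)
    if len(union) < 2:
        raise ValueError("selected clusters pool fewer than 2 genes")

    twoway = two_way_cluster(matrix, union, gene_set_name="combined")
    partition = cut_tree(twoway.sample_dendrogram, params.k_groups)
    naming_dend = average_linkage(euclidean_distances(matrix, "samples"))
    labels = _map_cluster_labels(naming_dend, partition, params, annotation)
    labels.name = "group"
    return GroupAssignment(
        labels=labels,
        signature_genes=union,
        provenance={
            "k_groups": params.k_groups,
            "n_signature_genes": len(union),
            "seed": params.seed,
            "per_set_scores": {
                name: [
                    round(c.score, 4)
                    for c in selected_clusters
                    if c.gene_set_name == name
                ]
                for name in {c.gene_set_name for c in selected_clusters}
            },
        },
    )


def run_pathway_grouping(
    matrix: ExpressionMatrix,
    gene_sets: GeneSetCollection,
    params: GroupingParams,
    annotation: SampleAnnotation | None = None,
) -> GroupAssignment:
    """Full pipeline: absent-probe filter, per-set two-way clustering and
    representative-cluster selection, pooled re-clustering into groups."""
    matrix = filter_absent_probes(matrix)
    large_sets = filter_by_set_size(gene_sets, params.min_set_size, matrix.gene_ids)
    if len(large_sets) == 0:
        raise ValueError(
            f"no gene set exceeds {params.min_set_size} genes on the array; "
            "consider the exploratory threshold of 20"
        )
    reference = reference_partition(matrix, params)

    selected: list[SelectedCluster] = []
    for name, members in large_sets.sets.items():
        genes = [g for g in members if g in matrix.data.columns]
        twoway = two_way_cluster(matrix, genes, gene_set_name=name)
        picks = select_representative_clusters(twoway, matrix, reference, params)
        logger.info(
            "gene set %s: selected %d cluster(s), scores %s",
            name,
            len(picks),
            [round(p.score, 3) for p in picks],
        )
        selected.extend(picks)
    if not selected:
        raise ValueError("no representative gene clusters found in any set")
    return combine_and_recluster(matrix, selected, params, annotation)


def stability_by_random_sets(
    matrix: ExpressionMatrix,
    assignment: GroupAssignment,
    params: GroupingParams,
) -> list[float]:
    """Re-cluster samples on random gene subsets and score each clustering
    against the assignment by adjusted Rand index."""
    rng = np.random.default_rng(params.seed)
    genes = matrix.gene_ids
    if params.random_set_size > len(genes):
        raise ValueError("random_set_size exceeds number of genes")
    scores = []
    for _ in range(params.n_random_sets):
        subset = list(rng.choice(genes, size=params.random_set_size, replace=False))
        part = _cluster_samples_on_genes(matrix, subset, params.k_groups)
        scores.append(adjusted_rand_index(part, assignment.labels))
    return scores
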