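"""SAM-type moderated differential statistic with permutation FDR.

For a two-class contrast the per-gene score is

    d_i = (mean1_i - mean2_i) / (s_i + s0)

where s_i is the pooled standard error of the mean difference and s0 a
small positive "fudge factor" that keeps low-variance genes from dominating
the ranking.  False-discovery q-values come from class-label permutations:
the expected number of null genes exceeding a gene's |d| (median across
permutations) divided by the observed count at that threshold.

Fold changes are reported as differences of log2 class means (the input is
already log2-scaled), i.e. fold_change = 2 ** (mean1 - mean2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .io_core import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class SamParams:
    s0_strategy: str = "median_si"  # "median_si" | "fixed" | "tusher_grid"
    s0_value: float = 0.0
    n_permutations: int = 100
    fold_change_min: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s0_strategy not in ("median_si", "fixed", "tusher_grid"):
            raise ValueError(f"unknown s0_strategy {self.s0_strategy!r}")
        if self.n_permutations < 10:
            raise ValueError("n_permutations must be >= 10")
        if self.fold_change_min < 1:
            raise ValueError("fold_change_min must be >= 1")


@dataclass
class DifferentialResult:
    """Per-gene d-scores, log2 fold changes and (optionally) q-values."""

    table: pd.DataFrame  # index gene_id; columns d_score, mean_log2_fc,
    #                      fold_change, s_i [, q_value]
    s0: float = 0.0
    contrast: str = ""

    @property
    def d_scores(self) -> pd.Series:
        return self.table["d_score"]

    @property
    def q_values(self) -> pd.Series:
        return self.table["q_value"]


def _contrast_masks(labels: pd.Series, contrast: tuple) -> tuple[np.ndarray, np.ndarray]:
    """``contrast`` is (group1_labels, group2_labels); either may be a single
    label or an iterable of labels (e.g. ("B", ("A", "C")))."""
    g1, g2 = contrast

    def as_set(g):
        return {g} if isinstance(g, str) else set(g)

    s1, s2 = as_set(g1), as_set(g2)
    m1 = labels.isin(s1).to_numpy()
    m2 = labels.isin(s2).to_numpy()
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError(
            f"each contrast class needs >= 2 samples, got {m1.sum()} vs {m2.sum()}"
        )
    if (m1 & m2).any():
        raise ValueError("contrast classes overlap")
    return m1, m2


def _d_and_s(values: np.ndarray, m1: np.ndarray, m2: np.ndarray):
    """Mean difference, pooled standard error and the raw arrays."""
    n1, n2 = int(m1.sum()), int(m2.sum())
    x1, x2 = values[m1], values[m2]
    mean1, mean2 = x1.mean(axis=0), x2.mean(axis=0)
    ss1 = ((x1 - mean1) ** 2).sum(axis=0)
    ss2 = ((x2 - mean2) ** 2).sum(axis=0)
    pooled_var = (ss1 + ss2) / (n1 + n2 - 2)
    s_i = np.sqrt((1.0 / n1 + 1.0 / n2) * pooled_var)
    return mean1 - mean2, s_i


def _resolve_s0(s_i: np.ndarray, diff: np.ndarray, params: SamParams) -> float:
    if params.s0_strategy == "fixed":
        return float(params.s0_value)
    if params.s0_strategy == "median_si":
        return float(np.median(s_i))
    # tusher_grid: pick the s_i percentile that minimises the coefficient of
    # variation of the d-score spread across bins of s_i
    percentiles = np.percentile(s_i, np.arange(0, 101, 5))
    best_s0, best_cv = 0.0, np.inf
    quantile_bins = np.quantile(s_i, np.linspace(0, 1, 11))
    bin_idx = np.clip(np.digitize(s_i, quantile_bins[1:-1]), 0, 9)
    for s0 in percentiles:
        d = diff / (s_i + s0)
        spreads = []
        for b in range(10):
            db = d[bin_idx == b]
            if len(db) > 1:
                spreads.append(np.median(np.abs(db - np.median(db))))
        spreads = np.asarray(spreads)
        if spreads.mean() == 0:
            continue
        cv = spreads.std() / spreads.mean()
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def sam_d_statistic(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    contrast: tuple,
    params: SamParams | None = None,
) -> DifferentialResult:
    """Compute per-gene d-scores and log2 fold changes for a two-class
    contrast (no q-values; see :func:`permutation_fdr`)."""
    params = params or SamParams()
    labels = labels.loc[matrix.sample_ids]
    m1, m2 = _contrast_masks(labels, contrast)
    diff, s_i = _d_and_s(matrix.values, m1, m2)
    s0 = _resolve_s0(s_i, diff, params)
    d = diff / (s_i + s0)
    table = pd.DataFrame(
        {
            "d_score": d,
            "mean_log2_fc": diff,
            "fold_change": np.exp2(diff),
            "s_i": s_i,
        },
        index=pd.Index(matrix.gene_ids, name="gene_id"),
    )
    name = f"{contrast[0]}_vs_{contrast[1]}"
    return DifferentialResult(table, s0=s0, contrast=name)


def permutation_fdr(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    contrast: tuple,
    params: SamParams | None = None,
) -> DifferentialResult:
    """d-scores plus permutation q-values.

    q(gene) = median over permutations of #{null |d| >= |d_gene|} divided by
    the observed #{|d| >= |d_gene|}, clipped to [0, 1] and monotonised so
    that q never decreases as |d| decreases.
    """
    params = params or SamParams()
    result = sam_d_statistic(matrix, labels, contrast, params)
    labels = labels.loc[matrix.sample_ids]
    m1, m2 = _contrast_masks(labels, contrast)
    used = m1 | m2
    values = matrix.values[used]
    n_used, n1 = int(used.sum()), int(m1.sum())

    n_perm = params.n_permutations
    n_distinct = comb(n_used, n1)
    if n_perm > n_distinct:
        warnings.warn(
            f"n_permutations={n_perm} exceeds {n_distinct} distinct label "
            "assignments; capping",
            stacklevel=2,
        )
        n_perm = n_distinct

    rng = np.random.default_rng(params.seed)
    obs_abs = np.abs(result.table["d_score"].to_numpy())
    order = np.argsort(-obs_abs)  # genes by decreasing |d|
    sorted_abs = obs_abs[order]
    # observed count of genes at or above each gene's threshold
    obs_counts = np.arange(1, len(obs_abs) + 1)

    null_counts = np.empty((n_perm, len(obs_abs)))
    base_m1 = np.zeros(n_used, dtype=bool)
    for p in range(n_perm):
        pick = rng.choice(n_used, size=n1, replace=False)
        pm1 = base_m1.copy()
        pm1[pick] = True
        pdiff, ps = _d_and_s(values, pm1, ~pm1)
        pd_abs = np.abs(pdiff / (ps + result.s0))
        pd_sorted = np.sort(pd_abs)
        # #{null |d| >= t} for each observed threshold t (descending t)
        null_counts[p] = len(pd_abs) - np.searchsorted(
            pd_sorted, sorted_abs, side="left"
        )
    med_fp = np.median(null_counts, axis=0)
    q_sorted = np.clip(med_fp / obs_counts, 0.0, 1.0)
    # monotonise: a gene with larger |d| never gets a larger q
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    result.table["q_value"] = q
    return result


def top_classifiers(
    result: DifferentialResult,
    params: SamParams | None = None,
    n_top: int = 50,
) -> pd.DataFrame:
    """Fold-change-filtered genes ranked by |d|, with regulation direction.

    Keeps genes whose fold change magnitude (in either direction) is at
    least ``fold_change_min``; the boundary is inclusive.
    """
    params = params or SamParams()
    table = result.table
    magnitude = np.exp2(np.abs(table["mean_log2_fc"]))
    kept = table[magnitude >= params.fold_change_min].copy()
    kept["direction"] = np.where(kept["mean_log2_fc"] >= 0, "up", "down")
    kept = kept.reindex(kept["d_score"].abs().sort_values(ascending=False).index)
    return kept.head(n_top)
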