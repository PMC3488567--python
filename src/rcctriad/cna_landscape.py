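"""Copy-number landscape: gain/loss calling on segment means, per-cytoband
status and cohort frequency profiles, and small-region/gene overlap reports.

Segment means beyond +-0.13 (strict) are called gains/losses; segments
shorter than 100 kb are discarded first as likely germline copy-number
variants.  Calls are projected onto cytogenetic bands (any >= 1 bp overlap),
bands hit by both a gain and a loss in the same case are flagged
concurrent, and cohort profiles report per-band gain/loss percentages.
Focal analysis keeps called segments below 5 Mb and lists the coding
regions they overlap.

All intervals are handled in one 0-based half-open convention (SEG input is
converted on load; UCSC cytoBand is natively half-open).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree


@dataclass
class CnaCallParams:
    gain_threshold: float = 0.13
    loss_threshold: float = -0.13
    cnv_min_size: int = 100_000
    small_region_max: int = 5_000_000

    def __post_init__(self) -> None:
        if not self.loss_threshold < 0 < self.gain_threshold:
            raise ValueError("need loss_threshold < 0 < gain_threshold")
        if not 0 < self.cnv_min_size < self.small_region_max:
            raise ValueError("need 0 < cnv_min_size < small_region_max")


@dataclass
class FrequencyProfile:
    """Per-cytoband gain/loss percentages over a case set."""

    table: pd.DataFrame  # index band; gain_percent, loss_percent, concurrent
    n_cases: int


def call_gains_losses(
    segments: pd.DataFrame, params: CnaCallParams | None = None
) -> pd.DataFrame:
    """Drop sub-CNV-size segments, then call each remaining segment gain
    (value > gain_threshold), loss (value < loss_threshold) or neutral."""
    params = params or CnaCallParams()
    seg = segments.copy()
    if (seg["start"] >= seg["end"]).any():
        raise ValueError("segment with start >= end")
    seg = seg[(seg["end"] - seg["start"]) >= params.cnv_min_size].copy()
    seg["status"] = np.select(
        [seg["value"] > params.gain_threshold, seg["value"] < params.loss_threshold],
        ["gain", "loss"],
        default="neutral",
    )
    return seg.reset_index(drop=True)


def _band_trees(cytobands: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in cytobands.groupby("chromosome"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e), band)
            for s, e, band in zip(sub["start"], sub["end"], sub["band"])
        )
    return trees


def map_to_cytobands(
    called_segments: pd.DataFrame, cytobands: pd.DataFrame
) -> pd.DataFrame:
    """Per-case, per-band status table.

    A band takes a case's status if any called non-neutral segment overlaps
    it by >= 1 bp; a band hit by both directions in one case is
    'concurrent'; untouched bands are 'neutral'.
    """
    trees = _band_trees(cytobands)
    bands = list(cytobands["band"])
    cases = sorted(called_segments["case_id"].unique())
    status = pd.DataFrame("neutral", index=pd.Index(cases, name="case_id"),
                          columns=bands)

    events = called_segments[called_segments["status"] != "neutral"]
    for row in events.itertuples():
        chrom = str(row.chromosome)
        if chrom not in trees:
            raise ValueError(f"segment chromosome {chrom!r} absent from cytoband map")
        for iv in trees[chrom].overlap(int(row.start), int(row.end)):
            band = iv.data
            current = status.at[row.case_id, band]
            if current == "neutral":
                status.at[row.case_id, band] = row.status
            elif current != row.status:
                status.at[row.case_id, band] = "concurrent"
    return status


def frequency_profile(band_status: pd.DataFrame) -> FrequencyProfile:
    """Cohort gain/loss percentages per band; concurrent cases count toward
    both directions."""
    if band_status.shape[0] < 1:
        raise ValueError("need at least one case")
    n = band_status.shape[0]
    gains = band_status.isin(["gain", "concurrent"]).sum(axis=0)
    losses = band_status.isin(["loss", "concurrent"]).sum(axis=0)
    concurrent = (band_status == "concurrent").any(axis=0)
    table = pd.DataFrame(
        {
            "gain_percent": 100.0 * gains / n,
            "loss_percent": 100.0 * losses / n,
            "concurrent_flag": concurrent,
        }
    )
    table.index.name = "band"
    return FrequencyProfile(table, n_cases=n)


def small_regions_and_genes(
    called_segments: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    params: CnaCallParams | None = None,
) -> pd.DataFrame:
    """Distinct called regions below the focal size limit, with the genes
    whose coding regions they overlap (>= 1 bp).

    Returns one row per distinct (chromosome, start, end, direction) region
    with the supporting case count, region length and overlapping genes.
    """
    params = params or CnaCallParams()
    events = called_segments[called_segments["status"] != "neutral"].copy()
    length = events["end"] - events["start"]
    events = events[(length < params.small_region_max)]

    gene_trees: dict[str, IntervalTree] = {}
    for chrom, sub in gene_annotation.groupby("chromosome"):
        gene_trees[str(chrom)] = IntervalTree.from_tuples(
            (int(s), int(e), g)
            for s, e, g in zip(sub["start"], sub["end"], sub["gene_id"])
        )

    grouped = events.groupby(["chromosome", "start", "end", "status"])
    rows = []
    for (chrom, start, end, direction), sub in grouped:
        tree = gene_trees.get(str(chrom))
        genes = sorted(iv.data for iv in tree.overlap(int(start), int(end))) if tree else []
        rows.append(
            {
                "chromosome": chrom,
                "start": int(start),
                "end": int(end),
                "length": int(end - start),
                "direction": direction,
                "n_cases": len(sub),
                "cases": ",".join(sorted(sub["case_id"])),
                "n_genes": len(genes),
                "genes": ",".join(genes),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["chromosome", "start", "end", "length", "direction",
                 "n_cases", "cases", "n_genes", "genes"],
    )
    return out.sort_values(["chromosome", "start", "end"]).reset_index(drop=True)


def region_summary(regions: pd.DataFrame) -> dict:
    """Counts mirroring the focal-region report: total distinct regions and
    gains/losses, plus distinct overlapped genes."""
    genes: set[str] = set()
    for g in regions["genes"]:
        if g:
            genes.update(g.split(","))
    return {
        "n_regions": int(len(regions)),
        "n_gains": int((regions["direction"] == "gain").sum()),
        "n_losses": int((regions["direction"] == "loss").sum()),
        "n_genes": len(genes),
    }
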