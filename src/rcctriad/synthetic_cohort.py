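"""Synthetic study generator.

Emulates a 146-array renal-cell-carcinoma cohort — 97 primary tumors, 15
metastases and 34 cancer cell lines — with three planted tumor groups (A, B,
C), group-specific signature genes at published fold-change ranges, a
genome-wide backdrop of moderately group-structured genes, a dedicated
shifted gene block that makes cell lines cluster apart, group-dependent
copy-number burden on a toy genome, group-ordered survival hazards, and
immunohistochemistry profiles obeying the MVD/DEK/MSH6 assignment rule.

Every generator is a pure function of (spec, seed): truth labels and gene
roles are returned alongside the data so recovery tests can score pipelines
against the planted structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import ExpressionMatrix, GeneSetCollection, SampleAnnotation

GROUPS = ("A", "B", "C")
CELL_LINE = "CELL_LINE"

GENE_ROLES = (
    "signature_B",
    "signature_A_vs_C",
    "pathway_structured",
    "cellline_block",
    "background",
    "absent",
)

#: toy genome: 22 autosomes of 100 Mb each
TOY_CHROM_LENGTH = 100_000_000
TOY_CHROMOSOMES = [str(i) for i in range(1, 23)]
TOY_BAND_SIZE = 5_000_000

# detection floor plumbing: absent genes sit at ABSENT_LEVEL, everything
# else is clipped at EXPRESSED_MIN (MAS5 log2 values are bounded below)
ABSENT_LEVEL = 1.0
EXPRESSED_MIN = 2.0


@dataclass
class CohortSpec:
    """Parameters of the synthetic study.

    Counts mirror the emulated cohort (97 primary RCC split 49/24/24 into
    groups A/B/C, 15 metastases, 34 cell lines); fold-change ranges are the
    published group-signature ranges on the natural scale.  ``n_genes`` is
    scaled down from the ~22,000-probe array to keep simulation fast.
    """

    n_primary: int = 97
    n_metastasis: int = 15
    n_cell_lines: int = 34
    group_sizes: tuple[int, int, int] = (49, 24, 24)
    n_genes: int = 2000
    n_pathway_sets: int = 4
    pathway_set_size: int = 200
    n_small_sets: int = 3
    small_set_sizes: tuple[int, ...] = (30, 60, 100)
    signature_genes_per_group: int = 40
    n_structured_genes: int = 200
    n_cellline_block: int = 80
    n_absent_genes: int = 50
    log2_fc_B_vs_AC_up: tuple[float, float] = (math.log2(5.2), math.log2(14.4))
    log2_fc_B_vs_AC_down: tuple[float, float] = (math.log2(5.7), math.log2(8.7))
    log2_fc_A_vs_C: tuple[float, float] = (math.log2(4.2), math.log2(16.0))
    structured_shift: tuple[float, float] = (1.0, 2.0)
    baseline_mean: float = 7.0
    noise_sd: float = 0.7
    cellline_shift: float = 2.0
    # copy-number events per tumor (Poisson means, ordered A < B <= C)
    cna_event_means: tuple[float, float, float] = (2.0, 5.0, 6.0)
    # survival: median overall survival in months per group, ordered A > B > C
    survival_medians: tuple[float, float, float] = (80.0, 45.0, 25.0)
    censor_window: tuple[float, float] = (6.0, 120.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(
            c <= 0
            for c in (
                self.n_primary,
                self.n_metastasis,
                self.n_cell_lines,
                self.n_genes,
            )
        ):
            raise ValueError("all cohort counts must be positive")
        if sum(self.group_sizes) != self.n_primary:
            raise ValueError(
                f"group_sizes {self.group_sizes} must sum to n_primary "
                f"({self.n_primary}); metastases are added on top"
            )
        for lo, hi in (
            self.log2_fc_B_vs_AC_up,
            self.log2_fc_B_vs_AC_down,
            self.log2_fc_A_vs_C,
            self.structured_shift,
        ):
            if lo > hi:
                raise ValueError("fold-change range must have lower <= upper")
        demand = (
            2 * self.signature_genes_per_group
            + self.n_structured_genes
            + self.n_cellline_block
            + self.n_absent_genes
        )
        if demand > self.n_genes:
            raise ValueError(
                f"signature gene demand ({demand}) exceeds n_genes ({self.n_genes})"
            )
        if len(self.small_set_sizes) != self.n_small_sets:
            raise ValueError("small_set_sizes must match n_small_sets")
        a, b, c = self.cna_event_means
        if not (a < b <= c):
            raise ValueError("cna_event_means must be ordered A < B <= C")


@dataclass
class GroundTruth:
    """Planted structure: per-sample labels, per-gene roles and effects."""

    sample_labels: pd.Series  # sample_id -> A/B/C/CELL_LINE
    gene_roles: pd.Series  # gene_id -> role
    gene_effects: pd.Series  # gene_id -> planted log2 shift (0 for background)
    cna_events: pd.DataFrame = field(default_factory=pd.DataFrame)

    def tumor_ids(self) -> list[str]:
        return list(self.sample_labels.index[self.sample_labels != CELL_LINE])

    def genes_with_role(self, role: str) -> list[str]:
        return list(self.gene_roles.index[self.gene_roles == role])


# deterministic subtype composition per group, scaled from the emulated
# cross-tabulation (groups enriched for clear-cell / papillary histology)
_SUBTYPE_COUNTS = {
    "A": {"ccRCC": 48, "pRCC": 1},
    "B": {"ccRCC": 17, "pRCC": 6, "chRCC": 1},
    "C": {"ccRCC": 10, "pRCC": 12, "chRCC": 1, "cc/pRCC": 1},
}


def _sample_frame(spec: CohortSpec, rng: np.random.Generator):
    """Sample ids, true labels and annotation rows."""
    ids, labels, classes, subtypes = [], [], [], []

    counter = 0
    for group, size in zip(GROUPS, spec.group_sizes):
        subs = []
        base = _SUBTYPE_COUNTS[group]
        for sub, cnt in base.items():
            subs.extend([sub] * cnt)
        # pad/trim to the requested group size, padding with ccRCC
        subs = (subs + ["ccRCC"] * size)[:size]
        rng.shuffle(subs)
        for sub in subs:
            counter += 1
            ids.append(f"P{counter:03d}")
            labels.append(group)
            classes.append("primary_tumor")
            subtypes.append(sub)

    for m in range(spec.n_metastasis):
        ids.append(f"M{m + 1:03d}")
        labels.append(GROUPS[m % 3])
        classes.append("metastasis")
        subtypes.append("ccRCC")

    for c in range(spec.n_cell_lines):
        ids.append(f"CL{c + 1:02d}")
        labels.append(CELL_LINE)
        classes.append("cell_line")
        subtypes.append("other")

    stage = np.where(rng.random(len(ids)) < 0.6, "pT1/pT2", "pT3/pT4")
    grade = rng.choice(["1", "2", "3", "4"], size=len(ids), p=[0.07, 0.44, 0.42, 0.07])
    sarcomatoid = np.where(rng.random(len(ids)) < 0.1, "yes", "no")
    is_cl = np.array(classes) == "cell_line"
    stage[is_cl] = "unknown"
    grade[is_cl] = "unknown"
    sarcomatoid[is_cl] = "unknown"

    ann = pd.DataFrame(
        {
            "sample_class": classes,
            "subtype": subtypes,
            "stage": stage,
            "grade": grade,
            "sarcomatoid": sarcomatoid,
        },
        index=pd.Index(ids, name="sample_id"),
    )
    truth = pd.Series(labels, index=ann.index, name="true_group")
    return ann, truth


def _assign_gene_roles(spec: CohortSpec, rng: np.random.Generator) -> pd.Series:
    gene_ids = [f"G{i:04d}" for i in range(spec.n_genes)]
    roles = np.array(["background"] * spec.n_genes, dtype=object)
    order = rng.permutation(spec.n_genes)
    pos = 0
    for role, count in (
        ("signature_B", spec.signature_genes_per_group),
        ("signature_A_vs_C", spec.signature_genes_per_group),
        ("pathway_structured", spec.n_structured_genes),
        ("cellline_block", spec.n_cellline_block),
        ("absent", spec.n_absent_genes),
    ):
        roles[order[pos : pos + count]] = role
        pos += count
    return pd.Series(roles, index=pd.Index(gene_ids, name="gene_id"), name="role")


def generate_expression(
    spec: CohortSpec,
) -> tuple[ExpressionMatrix, SampleAnnotation, GroundTruth]:
    """Simulate the log2 expression matrix with planted group structure.

    Signature genes receive additive log2 shifts drawn from the spec's
    fold-change ranges in their target group; structured genes carry smaller
    one-group-vs-rest shifts spread genome-wide; a disjoint block is shifted
    in cell lines only, so cell lines form their own cluster; absent genes
    sit at a constant sub-detection level in every sample.
    """
    rng = np.random.default_rng(spec.seed)
    ann, truth_labels = _sample_frame(spec, rng)
    roles = _assign_gene_roles(spec, rng)
    n_samples = len(ann)

    labels = truth_labels.to_numpy()
    values = rng.normal(spec.baseline_mean, spec.noise_sd, (n_samples, spec.n_genes))
    in_group = {g: labels == g for g in GROUPS}
    is_cell = labels == CELL_LINE
    role_arr = roles.to_numpy()
    effects = np.zeros(spec.n_genes)

    # group-B signature: up-regulated in B for ~2/3 of the genes, the rest
    # down-regulated, shift magnitudes drawn from the published ranges
    b_idx = np.flatnonzero(role_arr == "signature_B")
    n_up = int(round(len(b_idx) * 2 / 3))
    for j in b_idx[:n_up]:
        delta = rng.uniform(*spec.log2_fc_B_vs_AC_up)
        values[in_group["B"], j] += delta
        effects[j] = delta
    for j in b_idx[n_up:]:
        delta = rng.uniform(*spec.log2_fc_B_vs_AC_down)
        values[in_group["B"], j] -= delta
        effects[j] = -delta

    # A-vs-C signature: most genes high in A, a few high in C; the shift is
    # split symmetrically (+d/2 in A, -d/2 in C for an A-high gene) so the
    # planted A-C mean difference is d while B stays at baseline between
    # them — B separates from both, A sits nearer C than B
    ac_idx = np.flatnonzero(role_arr == "signature_A_vs_C")
    n_a_up = int(round(len(ac_idx) * 0.8))
    for rank, j in enumerate(ac_idx):
        delta = rng.uniform(*spec.log2_fc_A_vs_C)
        sign = 1.0 if rank < n_a_up else -1.0
        values[in_group["A"], j] += sign * delta / 2
        values[in_group["C"], j] -= sign * delta / 2
        effects[j] = sign * delta

    # genome-wide structured backdrop: each gene separates one group from
    # the rest with a moderate shift of random sign; most of it separates B,
    # so that B is the most distinct group on any representative gene subset
    # while A and C stay comparatively close
    st_idx = np.flatnonzero(role_arr == "pathway_structured")
    st_groups = rng.choice(GROUPS, size=len(st_idx), p=[0.2, 0.6, 0.2])
    for j, g in zip(st_idx, st_groups):
        delta = rng.uniform(*spec.structured_shift) * rng.choice([-1.0, 1.0])
        values[in_group[g], j] += delta
        effects[j] = delta

    # cell-line block: common shift making cell lines self-similar
    cl_idx = np.flatnonzero(role_arr == "cellline_block")
    values[np.ix_(is_cell, cl_idx)] += spec.cellline_shift
    effects[cl_idx] = spec.cellline_shift

    # clip expressed values at the platform floor, then plant absent genes
    if spec.noise_sd > 0:
        values = np.maximum(values, EXPRESSED_MIN)
    absent_idx = np.flatnonzero(role_arr == "absent")
    values[:, absent_idx] = ABSENT_LEVEL
    effects[absent_idx] = 0.0

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=ann.index, columns=roles.index)
    )
    truth = GroundTruth(
        sample_labels=truth_labels,
        gene_roles=roles,
        gene_effects=pd.Series(effects, index=roles.index, name="log2_effect"),
    )
    return matrix, SampleAnnotation(ann), truth


def generate_gene_sets(spec: CohortSpec, truth: GroundTruth) -> GeneSetCollection:
    """Pathway-like gene sets: large sets carry quotas of every planted
    signal class plus background; small sets contain background genes only.
    """
    rng = np.random.default_rng(spec.seed + 1)
    pools = {
        role: list(rng.permutation(truth.genes_with_role(role)))
        for role in ("signature_B", "signature_A_vs_C", "pathway_structured",
                     "cellline_block", "background")
    }

    def take(role: str, k: int) -> list[str]:
        picked, pools[role] = pools[role][:k], pools[role][k:]
        if len(picked) < k:
            raise ValueError(f"gene pool for {role!r} exhausted")
        return picked

    n = spec.n_pathway_sets
    sets: dict[str, list[str]] = {}
    names = ["Wnt", "Inflammation", "Angiogenesis", "Integrin"]
    for i in range(n):
        name = names[i] if i < len(names) else f"Pathway{i + 1}"
        members = (
            take("signature_B", spec.signature_genes_per_group // n)
            + take("signature_A_vs_C", spec.signature_genes_per_group // n)
            + take("pathway_structured", spec.n_structured_genes // n)
            + take("cellline_block", spec.n_cellline_block // n)
        )
        members += take("background", spec.pathway_set_size - len(members))
        rng.shuffle(members)
        sets[name] = members

    small_names = ["Apoptosis", "HIF_signaling", "Cysteine_biosynthesis"]
    for i, size in enumerate(spec.small_set_sizes):
        name = small_names[i] if i < len(small_names) else f"Small{i + 1}"
        sets[name] = take("background", size)

    return GeneSetCollection(sets, {k: "synthetic pathway" for k in sets})


def toy_cytobands() -> pd.DataFrame:
    """Uniform cytobands on the toy genome (0-based half-open, UCSC-style)."""
    rows = []
    for chrom in TOY_CHROMOSOMES:
        n_bands = TOY_CHROM_LENGTH // TOY_BAND_SIZE
        half = n_bands // 2
        for b in range(n_bands):
            arm, num = ("p", half - b) if b < half else ("q", b - half + 1)
            rows.append(
                {
                    "chromosome": chrom,
                    "start": b * TOY_BAND_SIZE,
                    "end": (b + 1) * TOY_BAND_SIZE,
                    "name": f"{arm}{num}",
                    "stain": "gneg",
                }
            )
    df = pd.DataFrame(rows)
    df["band"] = df["chromosome"] + df["name"]
    return df


def toy_gene_annotation(n_genes: int = 600, seed: int = 7) -> pd.DataFrame:
    """Toy coding-region intervals spread uniformly over the toy genome."""
    rng = np.random.default_rng(seed)
    chroms = rng.choice(TOY_CHROMOSOMES, size=n_genes)
    starts = rng.integers(0, TOY_CHROM_LENGTH - 100_000, size=n_genes)
    lengths = rng.integers(5_000, 100_000, size=n_genes)
    return pd.DataFrame(
        {
            "chromosome": chroms,
            "start": starts,
            "end": starts + lengths,
            "gene_id": [f"LOC{i:04d}" for i in range(n_genes)],
        }
    )


def generate_cna_segments(
    spec: CohortSpec, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Copy-number segments per tumor on the toy genome.

    Event counts are Poisson with group-dependent means (A < B <= C).  Event
    sizes mix sub-100 kb germline-variant decoys, sub-5 Mb focal regions and
    larger arm-level segments; event log-ratios fall beyond +-0.13, neutral
    filler segments within.  Returns (segments, planted_events); coordinates
    are 0-based half-open.
    """
    rng = np.random.default_rng(spec.seed + 2)
    mean_by_group = dict(zip(GROUPS, spec.cna_event_means))
    seg_rows, event_rows = [], []

    for sample_id, group in truth.sample_labels.items():
        if group == CELL_LINE:
            continue
        n_events = rng.poisson(mean_by_group[group])
        for _ in range(n_events):
            kind = rng.choice(["cnv_decoy", "focal", "broad"], p=[0.2, 0.6, 0.2])
            if kind == "cnv_decoy":
                length = int(rng.integers(5_000, 95_000))
            elif kind == "focal":
                length = int(rng.integers(150_000, 4_800_000))
            else:
                length = int(rng.integers(6_000_000, 30_000_000))
            chrom = rng.choice(TOY_CHROMOSOMES)
            start = int(rng.integers(0, TOY_CHROM_LENGTH - length))
            sign = rng.choice([-1.0, 1.0])
            value = sign * rng.uniform(0.2, 0.8)
            row = {
                "case_id": sample_id,
                "chromosome": chrom,
                "start": start,
                "end": start + length,
                "value": value,
            }
            seg_rows.append(row)
            event_rows.append({**row, "kind": kind, "group": group})
        # neutral filler segments (no real copy-number change)
        for _ in range(3):
            length = int(rng.integers(1_000_000, 10_000_000))
            chrom = rng.choice(TOY_CHROMOSOMES)
            start = int(rng.integers(0, TOY_CHROM_LENGTH - length))
            seg_rows.append(
                {
                    "case_id": sample_id,
                    "chromosome": chrom,
                    "start": start,
                    "end": start + length,
                    "value": rng.uniform(-0.1, 0.1),
                }
            )

    segments = pd.DataFrame(
        seg_rows, columns=["case_id", "chromosome", "start", "end", "value"]
    )
    events = pd.DataFrame(
        event_rows,
        columns=["case_id", "chromosome", "start", "end", "value", "kind", "group"],
    )
    return segments, events


def generate_clinical(
    spec: CohortSpec, truth: GroundTruth, assignable_fraction: float = 0.75
) -> pd.DataFrame:
    """Survival and IHC marker table for tumor samples.

    Survival times are exponential with group-ordered hazards (best outcome
    in A, worst in C) under uniform administrative censoring.  With
    probability ``assignable_fraction`` a tumor's MVD/DEK/MSH6 profile obeys
    its group's marker rule; otherwise it falls in a rule coverage gap
    (intermediate microvessel count, or DEK-negative with MSH6-positive).
    """
    if not 0 < assignable_fraction <= 1:
        raise ValueError("assignable_fraction must be in (0, 1]")
    rng = np.random.default_rng(spec.seed + 3)
    scale_by_group = {
        g: med / math.log(2) for g, med in zip(GROUPS, spec.survival_medians)
    }
    rows = []
    for sample_id, group in truth.sample_labels.items():
        if group == CELL_LINE:
            continue
        t_event = rng.exponential(scale_by_group[group])
        t_censor = rng.uniform(*spec.censor_window)
        time = max(min(t_event, t_censor), 0.01)
        event = int(t_event <= t_censor)

        if rng.random() < assignable_fraction:
            if group == "A":  # high MVD, DEK+ and MSH6+
                mvd = int(rng.integers(110, 300))
                dek = rng.uniform(5, 80)
                msh6 = rng.uniform(5, 80)
            elif group == "B":  # MSH6-negative, any MVD, any DEK
                mvd = int(rng.integers(110, 300) if rng.random() < 0.5
                          else rng.integers(0, 45))
                dek = rng.uniform(0, 80)
                msh6 = rng.uniform(0, 0.9)
            else:  # C: low MVD, DEK+ and MSH6+
                mvd = int(rng.integers(0, 45))
                dek = rng.uniform(5, 80)
                msh6 = rng.uniform(5, 80)
        else:
            # profiles the rule does not cover
            if rng.random() < 0.5:
                mvd = int(rng.integers(55, 96))  # indeterminate density
                dek = rng.uniform(5, 80)
                msh6 = rng.uniform(5, 80)
            else:
                mvd = int(rng.integers(110, 300) if rng.random() < 0.5
                          else rng.integers(0, 45))
                dek = rng.uniform(0, 0.9)  # DEK-negative ...
                msh6 = rng.uniform(5, 80)  # ... with MSH6-positive
        rows.append(
            {
                "sample_id": sample_id,
                "time": round(time, 2),
                "event": event,
                "mvd_count": mvd,
                "dek_pct": round(dek, 2),
                "msh6_pct": round(msh6, 2),
                "true_group": group,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def generate_study(spec: CohortSpec, assignable_fraction: float = 0.75):
    """All components of one synthetic study, keyed by artifact name."""
    matrix, annotation, truth = generate_expression(spec)
    gene_sets = generate_gene_sets(spec, truth)
    segments, cna_events = generate_cna_segments(spec, truth)
    truth.cna_events = cna_events
    clinical = generate_clinical(spec, truth, assignable_fraction)
    return {
        "matrix": matrix,
        "annotation": annotation,
        "truth": truth,
        "gene_sets": gene_sets,
        "segments": segments,
        "clinical": clinical,
    }
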