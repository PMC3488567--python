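"""Readers, writers and preprocessing filters for the subtyping pipeline.

External formats handled here: expression matrices (TSV and GCT 1.2), GMT
gene-set collections, SEG copy-number segment tables, UCSC ``cytoBand.txt``
maps, clinical/IHC tables, and YAML configuration.  The internal expression
convention is always samples x genes on the log2 scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

SAMPLE_CLASSES = ("primary_tumor", "metastasis", "cell_line")
SUBTYPES = ("ccRCC", "pRCC", "chRCC", "cc/pRCC", "other")

# header keywords used to auto-detect matrix orientation
_GENE_ROW_KEYWORDS = ("gene", "probe", "name", "feature")
_SAMPLE_ROW_KEYWORDS = ("sample", "array", "case")


class LoadError(ValueError):
    """Raised when an external file violates its format contract."""


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values, oriented samples x genes.

    ``data`` is a DataFrame indexed by sample id with gene ids as columns.
    Construction validates finiteness, uniqueness and minimum size.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise LoadError("duplicate sample ids")
        if self.data.columns.has_duplicates:
            raise LoadError("duplicate gene ids")
        if self.data.shape[0] < 2 or self.data.shape[1] < 2:
            raise LoadError(
                f"need at least 2 samples and 2 genes, got {self.data.shape}"
            )
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = self.data.columns[
                ~self.data.apply(lambda c: pd.api.types.is_numeric_dtype(c))
            ]
            raise LoadError(f"non-numeric expression column(s): {list(bad)[:5]}")
        if not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise LoadError(
                f"non-finite value at sample {self.data.index[i]!r}, "
                f"gene {self.data.columns[j]!r}"
            )
        self.data = self.data.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_genes(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(sample_ids)])

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(gene_ids)])


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics); lists are deduplicated on load."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise LoadError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def sizes(self) -> dict[str, int]:
        return {name: len(genes) for name, genes in self.sets.items()}


def _dedup_preserve(items: list[str]) -> list[str]:
    return list(dict.fromkeys(items))


# ---------------------------------------------------------------------------
# expression matrices


def _orient_samples_by_genes(df: pd.DataFrame, index_name: str) -> pd.DataFrame:
    """Decide whether rows are genes or samples from the header keyword."""
    name = (index_name or "").strip().lower()
    if any(k in name for k in _SAMPLE_ROW_KEYWORDS):
        return df
    if any(k in name for k in _GENE_ROW_KEYWORDS):
        return df.T
    # default: the common distribution convention is genes x samples
    return df.T


def read_expression(path, format: str | None = None) -> ExpressionMatrix:
    """Load an expression matrix from TSV or GCT 1.2.

    TSV files carry the row-axis name in the top-left header cell; a name
    containing "sample"/"array" means rows are samples, "gene"/"probe" (or
    anything else) means rows are genes.  Output is always samples x genes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format not in ("tsv", "gct"):
        raise ValueError(f"unknown expression format {format!r}")

    if format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if not version.startswith("#1.2"):
                raise LoadError(f"{path}: not a GCT 1.2 file (header {version!r})")
            dims = fh.readline().split()
            if len(dims) != 2:
                raise LoadError(f"{path}: malformed GCT dimension line")
            n_rows, n_cols = int(dims[0]), int(dims[1])
            body = pd.read_csv(fh, sep="\t", index_col=0)
        if "Description" in body.columns:
            body = body.drop(columns=["Description"])
        if body.shape != (n_rows, n_cols):
            raise LoadError(
                f"{path}: GCT declares {n_rows}x{n_cols} but body is "
                f"{body.shape[0]}x{body.shape[1]}"
            )
        df = body.T  # GCT is genes x samples
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = _orient_samples_by_genes(df, df.index.name)

    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            raise LoadError(
                f"{path}: non-numeric value in column {col!r}, row(s) "
                f"{list(bad)[:3]}"
            )
    return ExpressionMatrix(df)


def write_expression(matrix: ExpressionMatrix, path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        out = matrix.data.T  # distribute genes x samples
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")
    elif format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
            out = matrix.data.T.copy()
            out.insert(0, "Description", "na")
            out.index.name = "Name"
            out.to_csv(fh, sep="\t")
    else:
        raise ValueError(f"unknown expression format {format!r}")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gene_sets(path) -> GeneSetCollection:
    """Parse a GMT file: per line ``name<TAB>description<TAB>gene...``."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise LoadError(
                    f"{path}: line {lineno} has {len(fields)} fields, "
                    "expected at least 3 (name, description, genes...)"
                )
            name, desc, *genes = fields
            if name in sets:
                raise LoadError(f"{path}: duplicate set name {name!r} at line {lineno}")
            genes = _dedup_preserve([g for g in genes if g])
            if not genes:
                raise LoadError(f"{path}: set {name!r} (line {lineno}) has no genes")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# preprocessing filters


def filter_absent_probes(
    matrix: ExpressionMatrix, detection_floor: float | None = None
) -> ExpressionMatrix:
    """Drop genes at or below the detection floor in *every* sample.

    Stands in for array present/absent detection calls, which plain
    matrices do not carry: a gene is "absent across all samples" when it
    never rises above ``detection_floor`` (default: matrix minimum + 1e-6).
    """
    values = matrix.values
    if detection_floor is None:
        detection_floor = float(values.min()) + 1e-6
    present = (values > detection_floor).any(axis=0)
    if not present.any():
        raise ValueError("all genes fall below the detection floor")
    n_removed = int((~present).sum())
    if n_removed:
        logger.info("filter_absent_probes: removed %d all-absent genes", n_removed)
    return ExpressionMatrix(matrix.data.loc[:, present])


def filter_by_set_size(
    collection: GeneSetCollection,
    min_size: int,
    matrix_genes=None,
) -> GeneSetCollection:
    """Keep sets with strictly more than ``min_size`` genes.

    When ``matrix_genes`` is given, only member genes present on the array
    count toward the size (pathway databases list more genes than any one
    platform measures).
    """
    if min_size < 0:
        raise ValueError("min_size must be >= 0")
    genes = set(matrix_genes) if matrix_genes is not None else None
    kept: dict[str, list[str]] = {}
    for name, members in collection.sets.items():
        effective = [g for g in members if genes is None or g in genes]
        if len(effective) > min_size:
            kept[name] = members
    return GeneSetCollection(
        kept, {k: v for k, v in collection.descriptions.items() if k in kept}
    )


# ---------------------------------------------------------------------------
# sample annotation & clinical tables


@dataclass
class SampleAnnotation:
    """Per-sample class/subtype/stage/grade table indexed by sample_id."""

    table: pd.DataFrame

    REQUIRED = ("sample_class", "subtype")

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise LoadError("duplicate sample ids in annotation")
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise LoadError(f"annotation missing column {col!r}")
        bad = set(self.table["sample_class"]) - set(SAMPLE_CLASSES)
        if bad:
            raise LoadError(f"unknown sample_class values: {sorted(bad)}")

    def covers(self, matrix: ExpressionMatrix) -> bool:
        return set(matrix.sample_ids) <= set(self.table.index)

    def loc(self, sample_ids) -> pd.DataFrame:
        return self.table.loc[list(sample_ids)]


def read_annotation(path) -> SampleAnnotation:
    df = pd.read_csv(path, sep="\t", index_col="sample_id", dtype=str)
    return SampleAnnotation(df)


def write_annotation(annotation: SampleAnnotation, path) -> None:
    out = annotation.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


CLINICAL_REQUIRED = ("time", "event", "mvd_count", "dek_pct", "msh6_pct")


def read_clinical(path) -> pd.DataFrame:
    """Clinical/IHC TSV with mandatory survival and marker columns."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: clinical table missing column(s) {missing}")
    if (df["time"] <= 0).any():
        bad = df.index[df["time"] <= 0][:3]
        raise LoadError(f"{path}: non-positive survival time for {list(bad)}")
    return df


# ---------------------------------------------------------------------------
# copy-number segments (SEG) and cytobands (UCSC)

SEG_COLUMNS = ["case_id", "chromosome", "start", "end", "value"]


def _norm_chrom(chrom) -> str:
    s = str(chrom)
    return s[3:] if s.lower().startswith("chr") else s


def read_seg(path) -> pd.DataFrame:
    """Read a SEG table into the internal 0-based half-open convention.

    SEG coordinates are 1-based inclusive; ``start`` is shifted down by one
    so interval lengths are preserved.  Columns: case_id, chromosome (string,
    no 'chr' prefix), start, end, value (segment-mean log2 ratio).
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower().replace(".", "_"): c for c in df.columns}
    mapping = {}
    for target, aliases in {
        "case_id": ("id", "sample", "case_id", "sample_id"),
        "chromosome": ("chrom", "chromosome", "chr"),
        "start": ("loc_start", "start"),
        "end": ("loc_end", "end"),
        "value": ("seg_mean", "value", "mean"),
    }.items():
        for alias in aliases:
            if alias in cols:
                mapping[cols[alias]] = target
                break
        else:
            raise LoadError(f"{path}: SEG file missing a column for {target!r}")
    df = df.rename(columns=mapping)[SEG_COLUMNS]
    df["chromosome"] = df["chromosome"].map(_norm_chrom)
    df["start"] = df["start"].astype(int) - 1  # to 0-based half-open
    df["end"] = df["end"].astype(int)
    if (df["start"] >= df["end"]).any():
        raise LoadError(f"{path}: segment with start >= end")
    if not np.isfinite(df["value"]).all():
        raise LoadError(f"{path}: non-finite segment mean")
    return df


def write_seg(segments: pd.DataFrame, path) -> None:
    """Write internal half-open segments back out as 1-based inclusive SEG."""
    out = segments[SEG_COLUMNS].copy()
    out = out.rename(
        columns={
            "case_id": "ID",
            "chromosome": "chrom",
            "start": "loc.start",
            "end": "loc.end",
            "value": "seg.mean",
        }
    )
    out["loc.start"] = out["loc.start"].astype(int) + 1
    out.to_csv(path, sep="\t", index=False)


def read_cytobands(path, autosomes_only: bool = True) -> pd.DataFrame:
    """Read a UCSC cytoBand table (0-based half-open, its native convention).

    Returns columns chromosome, start, end, band (e.g. "3p25"), stain.
    With ``autosomes_only`` (default) chromosomes outside 1-22 are dropped.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chromosome", "start", "end", "name", "stain"],
        dtype={"chromosome": str},
        comment="#",
    )
    df["chromosome"] = df["chromosome"].map(_norm_chrom)
    if autosomes_only:
        df = df[df["chromosome"].isin([str(i) for i in range(1, 23)])]
    df = df.reset_index(drop=True)
    df["band"] = df["chromosome"] + df["name"].astype(str)
    return df


def read_gene_bed(path) -> pd.DataFrame:
    """BED intervals of gene coding regions: chromosome, start, end, gene_id."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 3],
        names=["chromosome", "start", "end", "gene_id"],
        dtype={"chromosome": str},
        comment="#",
    )
    df["chromosome"] = df["chromosome"].map(_norm_chrom)
    return df


# ---------------------------------------------------------------------------
# configuration


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise LoadError(f"{path}: config must be a YAML mapping")
    return cfg


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
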