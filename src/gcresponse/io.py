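"""Readers, writers and expression transforms for the pipeline's external formats.

Formats handled: TSV expression matrix (genes x samples, FPKM-UQ scale),
SEG-like segment tables (1-based inclusive coordinates, SEG convention),
CSV variant and clinical tables, and GMT gene-set files.  All readers accept
gzip-compressed input transparently (pandas infers compression from the
filename).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD")
MSI_MARKERS = ("BAT25", "MS05", "MS11")

CLINICAL_NUMERIC = ("age", "os_time", "pfs_time")
CLINICAL_EVENTS = ("os_event", "pfs_event")
CLINICAL_CATEGORICAL = ("gender", "histology", "tissue_type", "cT", "cN")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class StateError(ValueError):
    """Raised when a transform is applied to a matrix in the wrong state."""


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with an explicit transform state.

    ``transform_state`` is one of ``raw`` (non-negative FPKM-UQ-like values),
    ``log`` (natural log with offset) or ``zscore`` (per-gene standardised).
    """

    values: pd.DataFrame  # index = gene symbols, columns = sample ids
    transform_state: str = "raw"

    def __post_init__(self) -> None:
        if self.transform_state not in ("raw", "log", "zscore"):
            raise ValueError(f"unknown transform_state {self.transform_state!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.transform_state == "raw" and (self.values.to_numpy() < 0).any():
            raise ValueError("raw expression values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column gene symbols, header sample ids).

    Duplicate gene rows are collapsed by taking the per-sample maximum (a
    deterministic, conservative choice for signature scoring); the collapse
    is logged.  Non-numeric cells raise :class:`FormatError` naming the
    offending gene and sample.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty or df.shape[1] == 0:
        raise FormatError(f"{path}: empty expression matrix")
    df.index = df.index.astype(str)
    df.index.name = None
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            gene = bad[0] if len(bad) else df.index[df[col].isna()][0]
            raise FormatError(
                f"{path}: non-numeric value for gene {gene!r} in sample {col!r}"
            )
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        gene = df.index[df[col].isna()][0]
        raise FormatError(f"{path}: missing value for gene {gene!r} in sample {col!r}")
    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        logger.info("collapsing %d duplicate gene rows by max", n_dup)
        df = df.groupby(level=0, sort=False).max()
    return ExpressionMatrix(values=df.astype(float), transform_state="raw")


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    # %.17g keeps write->read an identity on float64 content
    m.values.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")


def log_offset_transform(m: ExpressionMatrix, offset: float = 0.01) -> ExpressionMatrix:
    """Elementwise natural log with a small offset: ``x -> ln(x + offset)``.

    The offset (default 0.01) keeps zero-expression genes finite.
    """
    if offset <= 0:
        raise ValueError("offset must be positive")
    if m.transform_state != "raw":
        raise StateError(f"expected raw matrix, got {m.transform_state}")
    return ExpressionMatrix(values=np.log(m.values + offset), transform_state="log")


def row_zscore(m: ExpressionMatrix) -> ExpressionMatrix:
    """Standardise each gene row to mean 0, sd 1; constant rows become all-zero."""
    if m.transform_state != "log":
        raise StateError(f"expected log matrix, got {m.transform_state}")
    vals = m.values.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    centred = vals - mean
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, centred / sd, 0.0)
    return ExpressionMatrix(
        values=pd.DataFrame(z, index=m.values.index, columns=m.values.columns),
        transform_state="zscore",
    )


# ---------------------------------------------------------------------------
# Copy-number segments
# ---------------------------------------------------------------------------

@dataclass
class SegmentProfile:
    """Per-sample copy-number segments, 1-based inclusive coordinates (SEG
    convention).  Segments on a chromosome must be sorted and non-overlapping."""

    sample_id: str
    segments: pd.DataFrame  # columns: chrom, start, end, total_cn

    def __post_init__(self) -> None:
        seg = self.segments
        required = ["chrom", "start", "end", "total_cn"]
        missing = [c for c in required if c not in seg.columns]
        if missing:
            raise ValueError(f"segment table missing columns {missing}")
        if (seg["start"] > seg["end"]).any():
            raise ValueError(f"{self.sample_id}: segment with start > end")
        if (seg["total_cn"] < 0).any():
            raise ValueError(f"{self.sample_id}: negative total copy number")
        for chrom, grp in seg.groupby("chrom", sort=False):
            srt = grp.sort_values("start")
            if (srt["start"].to_numpy()[1:] <= srt["end"].to_numpy()[:-1]).any():
                raise ValueError(
                    f"{self.sample_id}: overlapping segments on {chrom}"
                )
        self.segments = seg.sort_values(["chrom", "start"]).reset_index(drop=True)

    @property
    def n_segments(self) -> int:
        return len(self.segments)


def read_segments(path: str | Path) -> list[SegmentProfile]:
    """Read a SEG-like TSV: columns sample, chrom, start, end, total_cn."""
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={df.columns[0]: "sample"})
    required = {"sample", "chrom", "start", "end", "total_cn"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    profiles = []
    for sid, grp in df.groupby("sample", sort=False):
        profiles.append(
            SegmentProfile(
                sample_id=str(sid),
                segments=grp[["chrom", "start", "end", "total_cn"]].reset_index(drop=True),
            )
        )
    return profiles


def write_segments(profiles: Sequence[SegmentProfile], path: str | Path) -> None:
    frames = []
    for p in profiles:
        out = p.segments.copy()
        out.insert(0, "sample", p.sample_id)
        frames.append(out)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

@dataclass
class VariantTable:
    """Long-form variant records: sample_id, gene, marker_name, vaf, is_somatic."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        req = ["sample_id", "gene", "marker_name", "vaf", "is_somatic"]
        missing = [c for c in req if c not in self.records.columns]
        if missing:
            raise ValueError(f"variant table missing columns {missing}")
        vaf = self.records["vaf"].dropna()
        if ((vaf < 0) | (vaf > 1)).any():
            raise ValueError("vaf values must lie in [0, 1]")

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        return self.records[self.records["sample_id"] == sample_id]


def read_variants(path: str | Path) -> VariantTable:
    df = pd.read_csv(path)
    return VariantTable(records=df)


def write_variants(v: VariantTable, path: str | Path) -> None:
    v.records.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------

@dataclass
class ClinicalTable:
    """Per-sample clinical covariates, response category and survival endpoints.

    Missing values are permitted (NaN for numerics, "NA" or NaN for
    categories); imputation is deferred to feature assembly.
    """

    data: pd.DataFrame  # index = sample ids

    def __post_init__(self) -> None:
        df = self.data
        if "response_category" not in df.columns:
            raise ValueError("clinical table requires a response_category column")
        bad = set(df["response_category"].dropna()) - set(RESPONSE_CATEGORIES)
        if bad:
            raise ValueError(f"unknown response categories: {sorted(bad)}")
        for col in ("os_time", "pfs_time"):
            if col in df.columns and (df[col].dropna() < 0).any():
                raise ValueError(f"{col} must be non-negative")
        for col in CLINICAL_EVENTS:
            if col in df.columns:
                vals = set(df[col].dropna().astype(int)) - {0, 1}
                if vals:
                    raise ValueError(f"{col} must be binary 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return ClinicalTable(data=df)


def write_clinical(c: ClinicalTable, path: str | Path) -> None:
    c.data.to_csv(path, index_label="sample")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            self.genes = tuple(dict.fromkeys(self.genes))


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    @classmethod
    def from_dict(cls, d: Mapping[str, Iterable[str]]) -> "GeneSetCollection":
        return cls(
            sets={
                name: GeneSet(name=name, description="", genes=tuple(genes))
                for name, genes in d.items()
            }
        )


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, tab-separated name, description, members."""
    import gzip

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    sets: dict[str, GeneSet] = {}
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            sets[name] = GeneSet(name=name, description=desc, genes=tuple(genes))
    return GeneSetCollection(sets=sets)


def write_gene_sets(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in coll:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")
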