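"""Rule-based flags from targeted sequencing: MSI status, PGx, pathogens.

The microsatellite-instability rule counts mutated markers among BAT25,
MS05 and MS11: none mutated -> MSS, exactly one -> MSI-low, two or more ->
MSI-high.  Pathogen positivity operationalises "read count ten times higher
than other samples" as >= 10x the cohort median.  Associations with response
are tested by Fisher's exact test (two-sided by probability mass).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MSI_MARKERS, VariantTable

DEFAULT_PGX_GENES = ("GSTP1", "DPYD", "CYP2A6", "UGT1A1")
MSI_LEVELS = ("MSS", "MSI-low", "MSI-high")


@dataclass
class SampleFlags:
    """Per-sample rule-derived flags."""

    flags: pd.DataFrame  # columns: msi_status, pgx_positive, ebv_positive, hp_positive

    def __post_init__(self) -> None:
        if "msi_status" in self.flags.columns:
            bad = set(self.flags["msi_status"].dropna()) - set(MSI_LEVELS)
            if bad:
                raise ValueError(f"unknown MSI levels: {sorted(bad)}")


def classify_msi(v: VariantTable, sample_ids=None,
                 markers: tuple[str, ...] = MSI_MARKERS) -> pd.Series:
    """MSI status per sample from the count of mutated microsatellite markers."""
    unknown = set(markers) - set(MSI_MARKERS)
    if unknown:
        raise ValueError(f"unknown MSI markers configured: {sorted(unknown)}")
    rec = v.records
    hits = (
        rec[rec["marker_name"].isin(markers)]
        .groupby("sample_id")["marker_name"]
        .nunique()
    )
    if sample_ids is None:
        sample_ids = sorted(rec["sample_id"].unique())
    counts = hits.reindex(sample_ids).fillna(0).astype(int)
    status = np.where(counts == 0, "MSS",
                      np.where(counts == 1, "MSI-low", "MSI-high"))
    return pd.Series(status, index=counts.index, name="msi_status")


def flag_pgx(v: VariantTable, sample_ids=None,
             genes: tuple[str, ...] = DEFAULT_PGX_GENES) -> pd.Series:
    """True when a sample carries any variant record in the PGx gene list."""
    if not genes:
        raise ValueError("PGx gene list must be non-empty")
    rec = v.records
    positive = set(rec.loc[rec["gene"].isin(genes), "sample_id"])
    if sample_ids is None:
        sample_ids = sorted(rec["sample_id"].unique())
    return pd.Series([sid in positive for sid in sample_ids],
                     index=pd.Index(sample_ids), name="pgx_positive")


def call_pathogen(counts: pd.Series, factor: float = 10.0) -> pd.Series:
    """Flag samples whose pathogen read count is >= factor x cohort median.

    If the median is zero the comparison baseline falls back to the smallest
    positive count; an all-zero cohort yields all-negative with a warning.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    if len(counts) < 3:
        raise ValueError("need at least 3 samples to call pathogens")
    vals = counts.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("read counts must be non-negative")
    if not vals.any():
        warnings.warn("all pathogen counts are zero; no positives called")
        return pd.Series(False, index=counts.index, name=counts.name)
    baseline = float(np.median(vals))
    if baseline == 0:
        baseline = float(vals[vals > 0].min())
    return pd.Series(vals >= factor * baseline, index=counts.index,
                     name=counts.name)


def fisher_association(flag: pd.Series, labels: pd.Series) -> dict:
    """2x2 Fisher exact association between a binary flag and two-class labels.

    Returns the odds ratio (Haldane 0.5 correction when any cell is zero)
    and the two-sided p-value summing hypergeometric probability mass of
    tables as or more extreme.
    """
    aligned = pd.concat([flag.rename("flag"), labels.rename("label")],
                        axis=1).dropna()
    groups = sorted(aligned["label"].unique())
    states = sorted(aligned["flag"].astype(bool).unique())
    if len(groups) != 2 or len(states) != 2:
        raise ValueError("degenerate 2x2 table: need two labels and two flag states")
    table = np.array([
        [int(((aligned["flag"].astype(bool) == s) & (aligned["label"] == g)).sum())
         for g in groups]
        for s in [True, False]
    ])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    a, b = table[0]
    c, d = table[1]
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    odds_ratio = (a * d) / (b * c)
    return {"odds_ratio": float(odds_ratio), "p": float(p), "table": table}


def build_flags(variants: VariantTable, pathogen_counts: pd.DataFrame,
                sample_ids) -> SampleFlags:
    """Assemble the full per-sample flag table used by feature assembly."""
    flags = pd.DataFrame(index=pd.Index(sample_ids, name="sample"))
    flags["msi_status"] = classify_msi(variants, sample_ids)
    flags["pgx_positive"] = flag_pgx(variants, sample_ids)
    flags["ebv_positive"] = call_pathogen(pathogen_counts["EBV"].reindex(sample_ids))
    flags["hp_positive"] = call_pathogen(pathogen_counts["HP"].reindex(sample_ids))
    return SampleFlags(flags=flags)
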