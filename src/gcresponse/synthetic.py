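"""Synthetic multi-omics cohort with planted ground truth.

Generates every input the pipeline consumes — bulk expression as a mixture of
six immune reference profiles plus tumour background, copy-number segment
profiles realised from planted signature spectra, variant tables with MSI
markers and pharmacogenomic genes, pathogen read counts, clinical covariates
and survival times with class-dependent hazards — so that every downstream
stage can be tested against known truth without any controlled-access data.

The generative direction is label-first: each sample's Responder /
Non-responder label is drawn first and all molecular features are drawn
conditional on it, with the named effect coefficients tilting the
class-conditional distributions.  A cohort of 65 samples with a responder
probability of 29/65 mirrors the clinical setting the pipeline targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._utils import stream
from .io import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    SegmentProfile,
    VariantTable,
    write_clinical,
    write_expression,
    write_segments,
    write_variants,
)

CELL_TYPES = ("B", "CD4T", "CD8T", "NK", "Monocytes", "Neutrophils")

# 24-bin copy-number context scheme shared with cnsig (total-CN class x length class)
CN_CLASSES = ("0", "1", "2", "3-4", "5-8", "9+")
LENGTH_CLASSES = ("<100kb", "100kb-1Mb", "1-10Mb", ">10Mb")
CONTEXT_LABELS = tuple(f"CN{c}:{l}" for c in CN_CLASSES for l in LENGTH_CLASSES)


class ConfigError(ValueError):
    """Raised for invalid generator configuration."""


# ---------------------------------------------------------------------------
# Bundled synthetic references
# ---------------------------------------------------------------------------

def default_reference(n_markers_per_type: int = 15, n_background: int = 60) -> pd.DataFrame:
    """Block-structured 6-cell-type immune reference (genes x types).

    A synthetic stand-in for a leukocyte signature matrix: each cell type
    carries a block of marker genes expressed at 100 units in its own column
    and 1 unit elsewhere, plus shared background genes at 10 units everywhere.
    """
    rows = {}
    for t_idx, ctype in enumerate(CELL_TYPES):
        for m in range(n_markers_per_type):
            profile = np.ones(len(CELL_TYPES))
            profile[t_idx] = 100.0
            rows[f"{ctype}_M{m + 1:02d}"] = profile
    for b in range(n_background):
        rows[f"BG_{b + 1:03d}"] = np.full(len(CELL_TYPES), 10.0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(CELL_TYPES))


def default_gene_sets(config: "CohortConfig | None" = None) -> GeneSetCollection:
    """Gene sets matched to the synthetic gene universe.

    Includes inflammation / interferon programmes planted with class effects
    and an immune score set spanning all immune marker genes.
    """
    cfg = config or CohortConfig()
    infl = [f"INFL_{i + 1:02d}" for i in range(cfg.n_inflammatory_genes)]
    ifn = [f"IFN_{i + 1:02d}" for i in range(cfg.n_interferon_genes)]
    markers = [
        f"{ctype}_M{m + 1:02d}"
        for ctype in CELL_TYPES
        for m in range(cfg.n_markers_per_type)
    ]
    return GeneSetCollection.from_dict(
        {
            "INFLAMMATORY_RESPONSE": infl,
            "IL6_JAK_STAT3_SIGNALING": infl[: max(5, len(infl) // 2)],
            "INTERFERON_GAMMA_RESPONSE": ifn,
            "IMMUNE_SCORE": markers,
        }
    )


def default_cn_catalog() -> pd.DataFrame:
    """Bundled copy-number signature catalog on the 24-bin scheme.

    Declared stand-ins (names suffixed "-like") for three catalogued
    processes: CN1-like — diploid genome with long near-normal segments;
    CN4-like — whole-arm-scale gains at moderate copy number; CN9-like —
    focal high-level amplification on short segments (the pattern associated
    with elevated leukocyte fraction and hypoxia).
    """
    spectra = pd.DataFrame(0.0, index=["CN1-like", "CN4-like", "CN9-like"],
                           columns=list(CONTEXT_LABELS))
    # CN1-like: CN 2, long segments
    spectra.loc["CN1-like", "CN2:>10Mb"] = 0.55
    spectra.loc["CN1-like", "CN2:1-10Mb"] = 0.25
    spectra.loc["CN1-like", "CN1:>10Mb"] = 0.10
    spectra.loc["CN1-like", "CN3-4:>10Mb"] = 0.10
    # CN4-like: moderate gains, Mb-scale
    spectra.loc["CN4-like", "CN3-4:1-10Mb"] = 0.40
    spectra.loc["CN4-like", "CN3-4:100kb-1Mb"] = 0.25
    spectra.loc["CN4-like", "CN5-8:1-10Mb"] = 0.20
    spectra.loc["CN4-like", "CN2:1-10Mb"] = 0.15
    # CN9-like: focal amplification, short high-CN segments
    spectra.loc["CN9-like", "CN9+:<100kb"] = 0.35
    spectra.loc["CN9-like", "CN5-8:<100kb"] = 0.30
    spectra.loc["CN9-like", "CN9+:100kb-1Mb"] = 0.20
    spectra.loc["CN9-like", "CN1:<100kb"] = 0.15
    return spectra


# ---------------------------------------------------------------------------
# Configuration and truth containers
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Effect sizes are log-scale tilts applied to the class-conditional
    distributions: positive ``beta_neutrophil`` raises the responders'
    Dirichlet concentration on neutrophils, negative ``beta_cd4`` lowers it
    on CD4 T cells, ``beta_cn9`` raises responders' CN9-like exposure mean,
    and negative ``beta_inflammatory`` lowers responders' inflammatory
    programme expression.
    """

    n_samples: int = 65
    responder_prob: float = 29 / 65
    n_markers_per_type: int = 15
    n_background: int = 60
    n_inflammatory_genes: int = 20
    n_interferon_genes: int = 15
    noise_sd: float = 0.1              # sd of multiplicative log-normal noise
    programme_sd: float = 0.6          # per-sample programme-activity spread
    library_scale_sd: float = 0.2      # per-sample library size spread
    expression_scale: float = 1.0
    dirichlet_base: tuple = (2.0, 2.5, 2.0, 1.0, 2.0, 2.0)  # per CELL_TYPES
    beta_neutrophil: float = 1.0
    beta_cd4: float = -1.0
    beta_cn9: float = 0.7
    beta_inflammatory: float = -0.8
    fixed_fractions: Optional[np.ndarray] = None  # bypass Dirichlet (tests)
    # copy-number signatures
    exposure_mean_cn9: float = 20.0    # Non-responder mean; responders tilted
    exposure_mean_cn1: float = 40.0
    exposure_shape: float = 4.0
    # variants
    msi_marker_prob: float = 0.2
    pgx_gene_prob: float = 0.155
    driver_gene_probs: tuple = (("TP53", 0.5), ("MUC16", 0.3), ("ARID1A", 0.2))
    # pathogens
    ebv_background_mean: float = 2.0
    ebv_positive_prob: float = 0.046
    ebv_positive_mean: float = 150.0
    hp_background_mean: float = 5.0
    hp_positive_prob: float = 0.15
    hp_positive_mean: float = 250.0
    # survival (months)
    median_os_nonresponder: float = 8.0
    hazard_ratio: float = 2.5          # Non-responder vs Responder hazard
    censor_low: float = 12.0
    censor_high: float = 36.0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.dirichlet_base):
            raise ConfigError("Dirichlet concentrations must be positive")
        if self.n_samples < 2:
            raise ConfigError("need at least 2 samples")
        if not 0 < self.responder_prob < 1:
            raise ConfigError("responder_prob must be in (0, 1)")
        if self.noise_sd < 0 or self.library_scale_sd < 0:
            raise ConfigError("noise scales must be non-negative")

    @property
    def effects(self) -> dict[str, float]:
        return {
            "neutrophil_fraction": self.beta_neutrophil,
            "cd4_fraction": self.beta_cd4,
            "cn9_exposure": self.beta_cn9,
            "inflammatory_score": self.beta_inflammatory,
        }


@dataclass
class GroundTruth:
    fractions: pd.DataFrame        # samples x 6, rows on the simplex
    exposures: pd.DataFrame        # samples x 2 (CN9-like, CN1-like)
    spectra: pd.DataFrame          # 2 x 24 planted spectra
    response_logit_coefs: dict
    labels: pd.Series              # "Responder" / "Non-responder"
    hazard_ratio: float
    seed: int

    def __post_init__(self) -> None:
        rows = self.fractions.to_numpy()
        if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("truth fractions rows must sum to 1")
        if ((rows < 0) | (rows > 1)).any():
            raise ValueError("truth fractions must lie in [0, 1]")


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    segments: list[SegmentProfile]
    variants: VariantTable
    clinical: ClinicalTable
    pathogen_counts: pd.DataFrame  # samples x {EBV, HP}
    truth: GroundTruth

    def __post_init__(self) -> None:
        ids = set(self.expression.sample_ids)
        for other in (
            {p.sample_id for p in self.segments},
            set(self.clinical.sample_ids),
            set(self.pathogen_counts.index),
            set(self.truth.labels.index),
        ):
            if other != ids:
                raise ValueError("component sample id sets differ")

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _draw_fractions(cfg: CohortConfig, labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if cfg.fixed_fractions is not None:
        f = np.asarray(cfg.fixed_fractions, dtype=float)
        if f.shape != (cfg.n_samples, len(CELL_TYPES)):
            raise ConfigError("fixed_fractions has wrong shape")
        return f
    base = np.asarray(cfg.dirichlet_base, dtype=float)
    neut = CELL_TYPES.index("Neutrophils")
    cd4 = CELL_TYPES.index("CD4T")
    out = np.empty((cfg.n_samples, len(CELL_TYPES)))
    for i, is_resp in enumerate(labels):
        alpha = base.copy()
        if is_resp:
            alpha[neut] *= np.exp(cfg.beta_neutrophil)
            alpha[cd4] *= np.exp(cfg.beta_cd4)
        out[i] = rng.dirichlet(alpha)
    return out


def _mix_expression(cfg: CohortConfig, reference: pd.DataFrame, fractions: np.ndarray,
                    labels: np.ndarray, sample_ids: list[str],
                    rng: np.random.Generator) -> ExpressionMatrix:
    n = cfg.n_samples
    ref = reference.to_numpy()
    mixed = ref @ fractions.T  # genes x samples
    lib = np.exp(rng.normal(0.0, cfg.library_scale_sd, size=n))
    rows = {g: mixed[i] for i, g in enumerate(reference.index)}
    # transcriptional programmes carry per-sample biological variability on
    # top of the class tilt: activity is log-normal around the class mean,
    # so no single programme score separates the classes deterministically
    infl_level = np.exp(
        np.where(labels, cfg.beta_inflammatory, 0.0)
        + rng.normal(0.0, cfg.programme_sd, size=n))
    for i in range(cfg.n_inflammatory_genes):
        rows[f"INFL_{i + 1:02d}"] = 10.0 * infl_level
    ifn_level = np.exp(  # mild responder elevation
        np.where(labels, 0.4, 0.0) + rng.normal(0.0, cfg.programme_sd, size=n))
    for i in range(cfg.n_interferon_genes):
        rows[f"IFN_{i + 1:02d}"] = 10.0 * ifn_level
    vals = np.vstack(list(rows.values())) * cfg.expression_scale
    vals = vals * lib[None, :]
    if cfg.noise_sd > 0:
        vals = vals * np.exp(rng.normal(0.0, cfg.noise_sd, size=vals.shape))
    df = pd.DataFrame(vals, index=list(rows.keys()), columns=sample_ids)
    return ExpressionMatrix(values=df, transform_state="raw")


_CN_REPRESENTATIVE = {"0": 0, "1": 1, "2": 2, "3-4": 3, "5-8": 6, "9+": 10}
_LENGTH_RANGES = {
    "<100kb": (10_000, 100_000),
    "100kb-1Mb": (100_000, 1_000_000),
    "1-10Mb": (1_000_000, 10_000_000),
    ">10Mb": (10_000_000, 50_000_000),
}


def _realise_segments(sample_id: str, context_counts: np.ndarray,
                      rng: np.random.Generator) -> SegmentProfile:
    """Turn a 24-bin context count vector into a concrete segment profile.

    Each context bin maps to a representative total copy number and a length
    class; lengths are drawn uniformly within the class range and segments
    are laid down sequentially along chromosomes with gaps, so profiles are
    valid (sorted, non-overlapping) by construction.
    """
    chroms = [f"chr{i}" for i in range(1, 23)]
    cursor = {c: 1 for c in chroms}
    gap = 10_000
    recs = []
    bin_idx = 0
    for cn_class in CN_CLASSES:
        for length_class in LENGTH_CLASSES:
            count = int(context_counts[bin_idx])
            lo, hi = _LENGTH_RANGES[length_class]
            for _ in range(count):
                chrom = chroms[rng.integers(0, len(chroms))]
                length = int(rng.integers(lo, hi))
                start = cursor[chrom]
                end = start + length - 1
                cursor[chrom] = end + 1 + gap
                recs.append((chrom, start, end, _CN_REPRESENTATIVE[cn_class]))
            bin_idx += 1
    seg = pd.DataFrame(recs, columns=["chrom", "start", "end", "total_cn"])
    return SegmentProfile(sample_id=sample_id, segments=seg)


def _draw_survival(cfg: CohortConfig, labels: np.ndarray, rng: np.random.Generator):
    rate_nr = np.log(2.0) / cfg.median_os_nonresponder
    rate = np.where(labels, rate_nr / cfg.hazard_ratio, rate_nr)
    os_t = rng.exponential(1.0 / rate)
    pfs_t = rng.exponential(1.0 / (2.0 * rate))
    censor = rng.uniform(cfg.censor_low, cfg.censor_high, size=len(labels))
    os_event = (os_t <= censor).astype(int)
    pfs_event = (pfs_t <= censor).astype(int)
    return (np.minimum(os_t, censor), os_event,
            np.minimum(pfs_t, censor), pfs_event)


def simulate_cohort(config: CohortConfig | None = None, seed: int = 0) -> SyntheticCohort:
    """Generate a full synthetic cohort; identical (config, seed) gives an
    identical cohort (all randomness flows through named streams of the seed)."""
    cfg = config or CohortConfig()
    sample_ids = [f"GC{i + 1:03d}" for i in range(cfg.n_samples)]

    rng_labels = stream(seed, "labels")
    labels = rng_labels.random(cfg.n_samples) < cfg.responder_prob

    fractions = _draw_fractions(cfg, labels, stream(seed, "fractions"))
    reference = default_reference(cfg.n_markers_per_type, cfg.n_background)
    expression = _mix_expression(cfg, reference, fractions, labels, sample_ids,
                                 stream(seed, "expression"))

    # copy-number: class-tilted gamma exposures over the planted spectra
    catalog = default_cn_catalog()
    spectra = catalog.loc[["CN9-like", "CN1-like"]]
    rng_cn = stream(seed, "copy_number")
    mean_cn9 = np.where(labels, cfg.exposure_mean_cn9 * np.exp(cfg.beta_cn9),
                        cfg.exposure_mean_cn9)
    mean_cn1 = np.full(cfg.n_samples, cfg.exposure_mean_cn1)
    shape = cfg.exposure_shape
    exposures = np.column_stack([
        rng_cn.gamma(shape, mean_cn9 / shape),
        rng_cn.gamma(shape, mean_cn1 / shape),
    ])
    expected_counts = exposures @ spectra.to_numpy()
    counts = rng_cn.poisson(expected_counts)
    segments = [
        _realise_segments(sid, counts[i], rng_cn) for i, sid in enumerate(sample_ids)
    ]

    # variants: MSI markers, PGx genes, drivers
    rng_var = stream(seed, "variants")
    recs = []
    pgx_genes = ("GSTP1", "DPYD", "CYP2A6", "UGT1A1", "TYMS", "DPYS")
    for i, sid in enumerate(sample_ids):
        for marker in ("BAT25", "MS05", "MS11"):
            if rng_var.random() < cfg.msi_marker_prob:
                recs.append((sid, marker, marker, rng_var.beta(2, 5), 1))
        for gene in pgx_genes:
            if rng_var.random() < cfg.pgx_gene_prob:
                recs.append((sid, gene, "PGx", rng_var.beta(5, 5), 0))
        for gene, prob in cfg.driver_gene_probs:
            if rng_var.random() < prob:
                recs.append((sid, gene, "SNV", rng_var.beta(2, 5), 1))
    variants = VariantTable(records=pd.DataFrame(
        recs, columns=["sample_id", "gene", "marker_name", "vaf", "is_somatic"]))

    # pathogen read counts
    rng_path = stream(seed, "pathogens")
    ebv = rng_path.poisson(cfg.ebv_background_mean, cfg.n_samples).astype(float)
    ebv_pos = rng_path.random(cfg.n_samples) < cfg.ebv_positive_prob
    ebv[ebv_pos] = rng_path.poisson(cfg.ebv_positive_mean, int(ebv_pos.sum()))
    hp = rng_path.poisson(cfg.hp_background_mean, cfg.n_samples).astype(float)
    hp_pos = rng_path.random(cfg.n_samples) < cfg.hp_positive_prob
    hp[hp_pos] = rng_path.poisson(cfg.hp_positive_mean, int(hp_pos.sum()))
    pathogen_counts = pd.DataFrame(
        {"EBV": ebv.astype(int), "HP": hp.astype(int)}, index=sample_ids)

    # clinical covariates and survival
    rng_clin = stream(seed, "clinical")
    os_t, os_e, pfs_t, pfs_e = _draw_survival(cfg, labels, stream(seed, "survival"))
    age = np.clip(rng_clin.normal(np.where(labels, 67, 63), 10), 33, 84).round(0)
    gender = rng_clin.choice(["Male", "Female"], cfg.n_samples, p=[0.69, 0.31])
    histology = rng_clin.choice(["Intestinal", "Diffuse", "NEC"], cfg.n_samples,
                                p=[0.68, 0.29, 0.03])
    tissue = rng_clin.choice(["Tub", "Por", "Sig", "Muc", "NEC"], cfg.n_samples,
                             p=[0.51, 0.18, 0.22, 0.06, 0.03])
    ct = rng_clin.choice(["2", "3", "4a", "4b"], cfg.n_samples,
                         p=[0.03, 0.22, 0.63, 0.12])
    cn = rng_clin.choice(["0", "1", "2", "3"], cfg.n_samples,
                         p=[0.12, 0.25, 0.25, 0.38])
    response = np.where(
        labels, "PR",
        np.where(rng_clin.random(cfg.n_samples) < 16 / 35, "SD", "PD"))
    clin = pd.DataFrame(
        {
            "age": age,
            "gender": gender,
            "histology": histology,
            "tissue_type": tissue,
            "cT": ct,
            "cN": cn,
            "response_category": response,
            "os_time": os_t.round(3),
            "os_event": os_e,
            "pfs_time": pfs_t.round(3),
            "pfs_event": pfs_e,
        },
        index=sample_ids,
    )
    # a sprinkle of missingness, as real clinical tables carry NA rows
    if cfg.n_samples >= 30:
        clin.iloc[int(cfg.n_samples * 0.4), clin.columns.get_loc("age")] = np.nan
        clin.iloc[int(cfg.n_samples * 0.7), clin.columns.get_loc("cT")] = np.nan

    truth = GroundTruth(
        fractions=pd.DataFrame(fractions, index=sample_ids, columns=list(CELL_TYPES)),
        exposures=pd.DataFrame(exposures, index=sample_ids,
                               columns=["CN9-like", "CN1-like"]),
        spectra=spectra,
        response_logit_coefs=cfg.effects,
        labels=pd.Series(np.where(labels, "Responder", "Non-responder"),
                         index=sample_ids, name="label"),
        hazard_ratio=cfg.hazard_ratio,
        seed=seed,
    )
    return SyntheticCohort(
        expression=expression,
        segments=segments,
        variants=variants,
        clinical=ClinicalTable(data=clin),
        pathogen_counts=pathogen_counts,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Synthetic single cells (neutrophil module inputs)
# ---------------------------------------------------------------------------

@dataclass
class SingleCellConfig:
    """Archetype-based single-cell counts generator.

    Each archetype elevates its marker set around a negative-binomial mean;
    dropout zeroes counts Bernoulli-wise; a contamination fraction of cells
    additionally expresses lymphoid lineage markers, emulating sorting
    impurities that the lineage-exclusion filter must remove.
    """

    archetypes: dict = field(default_factory=dict)  # name -> marker gene list
    cells_per_cluster: int = 150
    marker_mean: float = 8.0
    base_mean: float = 0.3
    housekeeping_mean: float = 2.0
    nb_dispersion: float = 2.0
    dropout: float = 0.3
    contamination_fraction: float = 0.02
    mito_high_fraction: float = 0.05
    n_housekeeping: int = 30
    n_samples: int = 4

    def __post_init__(self) -> None:
        if not self.archetypes:
            from .neutrophil import DEFAULT_MARKER_PANEL

            self.archetypes = {
                f"{name}-like": list(genes)
                for name, genes in DEFAULT_MARKER_PANEL.items()
                if name != "lineage_exclusion"
            }
        if not self.archetypes:
            raise ConfigError("archetype list is empty")
        if not 0.0 <= self.dropout <= 1.0:
            raise ConfigError("dropout must lie in [0, 1]")


LINEAGE_GENES = ("CD3E", "CD19", "NCAM1", "CD8A", "CD4")
IG_GENES = ("IGHA1", "IGKC")
MITO_GENES = ("MT-CO1", "MT-ND1", "MT-CYB")


def simulate_single_cells(config: SingleCellConfig | None = None, seed: int = 0):
    """Simulate a neutrophil-focused single-cell counts matrix.

    Returns ``(CellMatrix, truth_labels)`` where truth labels give each
    cell's generating archetype ("contaminant" for planted lineage-marker
    cells).  Deterministic per seed.
    """
    from .neutrophil import CellMatrix

    cfg = config or SingleCellConfig()
    rng = stream(seed, "single_cells")

    marker_genes = sorted({g for genes in cfg.archetypes.values() for g in genes})
    hk = [f"HK_{i + 1:02d}" for i in range(cfg.n_housekeeping)]
    genes = marker_genes + hk + list(LINEAGE_GENES) + list(IG_GENES) + list(MITO_GENES)
    gene_idx = {g: i for i, g in enumerate(genes)}

    n_cells = cfg.cells_per_cluster * len(cfg.archetypes)
    means = np.full((len(genes), n_cells), cfg.base_mean)
    # lymphoid lineage and immunoglobulin genes are silent in genuine
    # neutrophils; only planted contaminants express them
    for g in (*LINEAGE_GENES, *IG_GENES):
        means[gene_idx[g], :] = 0.0
    labels = []
    col = 0
    for name, markers in cfg.archetypes.items():
        for _ in range(cfg.cells_per_cluster):
            for g in markers:
                means[gene_idx[g], col] = cfg.marker_mean
            for g in hk:
                means[gene_idx[g], col] = cfg.housekeeping_mean
            labels.append(name)
            col += 1
    labels = np.array(labels)

    r = cfg.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + means)).astype(np.int64)
    if cfg.dropout > 0:
        counts = counts * (rng.random(counts.shape) >= cfg.dropout)

    # planted lineage contamination
    contam = rng.random(n_cells) < cfg.contamination_fraction
    for j in np.flatnonzero(contam):
        g = LINEAGE_GENES[rng.integers(0, len(LINEAGE_GENES))]
        counts[gene_idx[g], j] += 1 + rng.poisson(3)
    labels = np.where(contam, "contaminant", labels)

    # mitochondrial counts tuned to target fractions (a planted high-mito tail)
    mito_frac = rng.beta(2, 30, size=n_cells)
    high = rng.random(n_cells) < cfg.mito_high_fraction
    mito_frac[high] = rng.beta(20, 8, size=int(high.sum()))  # mean ~0.7
    non_mito_tot = counts.sum(axis=0)
    mito_tot = np.round(non_mito_tot * mito_frac / np.maximum(1e-12, 1 - mito_frac))
    for k, g in enumerate(MITO_GENES):
        share = mito_tot // len(MITO_GENES) + (k < mito_tot % len(MITO_GENES))
        counts[gene_idx[g], :] = share.astype(np.int64)

    cell_ids = [f"cell_{j + 1:04d}" for j in range(n_cells)]
    samples = [f"P{(j % cfg.n_samples) + 1}" for j in range(n_cells)]
    obs = pd.DataFrame(
        {"sample": samples, "cluster": labels}, index=cell_ids)
    cm = CellMatrix(counts=counts, gene_ids=list(genes), cell_ids=cell_ids, obs=obs)
    return cm, pd.Series(labels, index=cell_ids, name="truth_cluster")


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Emit the cohort as plain-text files consumed unchanged by the CLI."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "segments": outdir / "segments.seg",
        "variants": outdir / "variants.csv",
        "clinical": outdir / "clinical.csv",
        "pathogens": outdir / "pathogens.csv",
        "truth": outdir / "truth.json",
    }
    write_expression(cohort.expression, paths["expression"])
    write_segments(cohort.segments, paths["segments"])
    write_variants(cohort.variants, paths["variants"])
    write_clinical(cohort.clinical, paths["clinical"])
    cohort.pathogen_counts.to_csv(paths["pathogens"], index_label="sample")
    truth = cohort.truth
    payload = {
        "fractions": truth.fractions.to_dict(orient="index"),
        "exposures": truth.exposures.to_dict(orient="index"),
        "spectra": truth.spectra.to_dict(orient="index"),
        "response_logit_coefs": truth.response_logit_coefs,
        "labels": truth.labels.to_dict(),
        "hazard_ratio": truth.hazard_ratio,
        "seed": truth.seed,
    }
    paths["truth"].write_text(json.dumps(payload, indent=1, sort_keys=True))
    return paths
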