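"""Single-cell neutrophil analysis: QC, normalisation, marker scoring,
cosine annotation, lineage exclusion, tumour-role fractions, and the
square-root-of-product bulk signature.

Cluster identities are taken as input (from upstream clustering or planted
truth); this module scores and annotates them.  Tumour-associated
neutrophil (TAN) states range from tumour-promoting (NET-forming,
chemokine-high) to tumour-suppressing (MHC-II-high antigen presenters); the
marker panel below encodes the published state markers, and the default
role map assigns TAN1/NETosis-like states to the pro-tumour class and
TAN2-like (antigen-presenting) states to the anti-tumour class.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._utils import cosine
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

# TAN4 carries both spellings of the ribosomal marker (PRS2 / RPS2), as the
# source lists disagree.
DEFAULT_MARKER_PANEL: dict[str, tuple[str, ...]] = {
    "TAN1": ("CXCL8", "CXCL1", "CXCL2", "ICAM1", "CD44"),
    "TAN2": ("HLA-DRA", "CD74", "HLA-DPB1"),
    "TAN3": ("PLIN2", "PLAU"),
    "TAN4": ("RPL10", "PRS2", "RPS2", "RPS18", "RPL3"),
    "NETosis": ("PROK2", "MME"),
    "lineage_exclusion": ("CD3E", "CD19", "NCAM1", "CD8A", "CD4"),
}

DEFAULT_ROLE_MAP: dict[str, str] = {
    "TAN1-like": "pro-tumor",
    "NETosis-like": "pro-tumor",
    "TAN2-like": "anti-tumor",
}

ROLES = ("pro-tumor", "anti-tumor", "other")
MITO_PREFIX = "MT-"
IG_PREFIXES = ("IGH", "IGK", "IGL")


@dataclass
class CellMatrix:
    """Genes x cells integer UMI counts with per-cell annotations.

    ``obs`` is indexed by cell id and may carry ``sample``, ``cluster`` and
    ``mito_fraction`` columns; the mitochondrial fraction is computed from
    genes with the configured symbol prefix when absent.
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    obs: pd.DataFrame = field(default_factory=pd.DataFrame)
    mito_prefix: str = MITO_PREFIX

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("counts shape does not match gene/cell ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.obs.empty:
            self.obs = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell"))
        if "mito_fraction" not in self.obs.columns:
            self.obs = self.obs.copy()
            self.obs["mito_fraction"] = self.mito_fractions()

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def mito_fractions(self) -> np.ndarray:
        mito = np.array([g.startswith(self.mito_prefix) for g in self.gene_ids])
        totals = self.counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, self.counts[mito].sum(axis=0) / totals, 0.0)
        return frac

    def subset(self, gene_mask=None, cell_mask=None) -> "CellMatrix":
        gm = np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask)
        cm = np.ones(self.n_cells, bool) if cell_mask is None else np.asarray(cell_mask)
        return CellMatrix(
            counts=self.counts[np.ix_(gm, cm)],
            gene_ids=[g for g, k in zip(self.gene_ids, gm) if k],
            cell_ids=[c for c, k in zip(self.cell_ids, cm) if k],
            obs=self.obs.loc[cm].copy(),
            mito_prefix=self.mito_prefix,
        )


@dataclass
class NormalizedCells:
    """Log-normalised expression: per cell ln(1 + count * scale / total)."""

    values: np.ndarray  # genes x cells, float
    gene_ids: list[str]
    cell_ids: list[str]
    obs: pd.DataFrame
    scale: float


def qc_filter(cm: CellMatrix, min_cells_per_gene: int = 3,
              min_genes_per_cell: int = 100, max_mito: float = 0.5) -> CellMatrix:
    """Standard count-matrix QC, gene filter applied before the cell filter.

    Removes genes expressed in fewer than ``min_cells_per_gene`` cells, then
    cells expressing fewer than ``min_genes_per_cell`` genes or with a
    mitochondrial fraction above ``max_mito``.  Idempotent: a second
    application removes nothing.
    """
    if min_cells_per_gene <= 0 or min_genes_per_cell <= 0:
        raise ValueError("QC thresholds must be positive")
    expressed = cm.counts > 0
    gene_keep = expressed.sum(axis=1) >= min_cells_per_gene
    after_genes = cm.subset(gene_mask=gene_keep)
    genes_per_cell = (after_genes.counts > 0).sum(axis=0)
    mito = after_genes.obs["mito_fraction"].to_numpy()
    cell_keep = (genes_per_cell >= min_genes_per_cell) & (mito <= max_mito)
    logger.info("QC removed %d genes and %d cells",
                int((~gene_keep).sum()), int((~cell_keep).sum()))
    if not cell_keep.any():
        raise ValueError(
            f"QC removed every cell (genes/cell median "
            f"{np.median(genes_per_cell):.0f}, mito median {np.median(mito):.2f})")
    return after_genes.subset(cell_mask=cell_keep)


def log_normalize(cm: CellMatrix, scale: float = 10_000.0) -> NormalizedCells:
    """Global-scaling log normalisation: ln(1 + count x scale / cell total)."""
    totals = cm.counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        bad = [c for c, t in zip(cm.cell_ids, totals) if t == 0]
        raise ValueError(f"zero-total cells (run QC first): {bad[:5]}")
    vals = np.log1p(cm.counts * (scale / totals)[None, :])
    return NormalizedCells(values=vals, gene_ids=list(cm.gene_ids),
                           cell_ids=list(cm.cell_ids), obs=cm.obs.copy(),
                           scale=scale)


def score_markers(norm: NormalizedCells,
                  panel: dict[str, tuple[str, ...]] | None = None,
                  cluster_key: str = "cluster") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean normalised expression of each marker set, per cell and per cluster.

    A set with no member present is scored as missing (NaN), not zero.
    Returns ``(per_cell, per_cluster)`` score tables.
    """
    panel = dict(panel or DEFAULT_MARKER_PANEL)
    panel.pop("lineage_exclusion", None)
    gene_idx = {g: i for i, g in enumerate(norm.gene_ids)}
    per_cell = {}
    for name, genes in panel.items():
        present = [gene_idx[g] for g in genes if g in gene_idx]
        missing = len(genes) - len(present)
        if missing:
            logger.info("marker set %s: %d/%d genes missing", name, missing, len(genes))
        if not present:
            per_cell[name] = np.full(len(norm.cell_ids), np.nan)
            continue
        per_cell[name] = norm.values[present].mean(axis=0)
    cells = pd.DataFrame(per_cell, index=norm.cell_ids)
    if cluster_key in norm.obs.columns:
        clusters = cells.groupby(norm.obs[cluster_key]).mean()
    else:
        clusters = pd.DataFrame(columns=cells.columns)
    return cells, clusters


def cluster_centroids(norm: NormalizedCells, cluster_key: str = "cluster") -> pd.DataFrame:
    """Mean normalised expression per cluster (genes x clusters)."""
    if cluster_key not in norm.obs.columns:
        raise ValueError(f"obs lacks a {cluster_key!r} column")
    out = {}
    for cl, idx in norm.obs.groupby(cluster_key).groups.items():
        mask = norm.obs.index.isin(idx)
        if not mask.any():
            raise ValueError(f"cluster {cl!r} is empty")
        out[cl] = norm.values[:, mask].mean(axis=1)
    return pd.DataFrame(out, index=norm.gene_ids)


def annotate_by_cosine(centroids: pd.DataFrame, reference: pd.DataFrame,
                       threshold: float = 0.6) -> pd.DataFrame:
    """Label each cluster centroid by its argmax-cosine reference profile.

    Clusters below the similarity threshold are labelled "Unassigned".  The
    full cluster x reference similarity matrix is returned alongside.
    """
    shared = centroids.index.intersection(reference.index)
    if len(shared) < 20:
        raise ValueError(f"only {len(shared)} genes shared with reference (need >= 20)")
    c = centroids.loc[shared]
    r = reference.loc[shared]
    sims = pd.DataFrame(
        [[cosine(c[cl].to_numpy(), r[ref].to_numpy()) for ref in r.columns]
         for cl in c.columns],
        index=c.columns, columns=r.columns)
    labels = []
    for cl in sims.index:
        best = sims.loc[cl].idxmax()
        sim = float(sims.loc[cl, best])
        labels.append({"cluster": cl,
                       "label": best if sim >= threshold else "Unassigned",
                       "similarity": sim})
    out = pd.DataFrame(labels).set_index("cluster")
    out.attrs["similarity_matrix"] = sims
    return out


def lineage_exclusion_filter(cm: CellMatrix,
                             lineage_genes=DEFAULT_MARKER_PANEL["lineage_exclusion"],
                             ig_prefixes=IG_PREFIXES,
                             ig_quantile: float = 0.95,
                             ig_min_mean: float = 1.0,
                             cluster_key: str = "cluster") -> CellMatrix:
    """Remove lymphoid-contaminant cells and immunoglobulin-high clusters.

    Cells with any nonzero count on a lineage marker (T/B/NK genes) are
    removed.  Clusters whose mean immunoglobulin count strictly exceeds both
    the ``ig_quantile`` quantile of cluster means and the absolute floor
    ``ig_min_mean`` are removed wholesale — a deterministic surrogate for
    the judgement call of dropping plasma-cell-contaminated clusters (the
    floor stops the quantile rule from firing on IG-silent data, where some
    cluster is always the largest).
    """
    gene_idx = {g: i for i, g in enumerate(cm.gene_ids)}
    lin_rows = [gene_idx[g] for g in lineage_genes if g in gene_idx]
    contaminated = np.zeros(cm.n_cells, dtype=bool)
    if lin_rows:
        contaminated = (cm.counts[lin_rows] > 0).any(axis=0)
    ig_rows = [i for i, g in enumerate(cm.gene_ids)
               if any(g.startswith(p) for p in ig_prefixes)]
    cluster_drop = np.zeros(cm.n_cells, dtype=bool)
    if ig_rows and cluster_key in cm.obs.columns:
        ig_mean = pd.Series(cm.counts[ig_rows].mean(axis=0), index=cm.obs.index)
        cluster_means = ig_mean.groupby(cm.obs[cluster_key]).mean()
        if len(cluster_means) > 1:
            cut = max(cluster_means.quantile(ig_quantile), ig_min_mean)
            bad_clusters = set(cluster_means[cluster_means > cut].index)
            if bad_clusters:
                cluster_drop = cm.obs[cluster_key].isin(bad_clusters).to_numpy()
    keep = ~(contaminated | cluster_drop)
    logger.info("lineage exclusion removed %d cells (%d marker-positive, "
                "%d in immunoglobulin-high clusters)",
                int((~keep).sum()), int(contaminated.sum()), int(cluster_drop.sum()))
    return cm.subset(cell_mask=keep)


def sqrt_product_signature(expr: ExpressionMatrix, genes, epsilon: float = 0.01,
                           exponent: float = 2.0) -> pd.Series:
    """Per-sample signature: the ``exponent``-th root of the product of the
    listed genes' expression (offset by epsilon), computed in log space.

    ``exponent=2`` is the literal square root of the product;
    ``exponent=len(genes)`` gives the geometric mean.  Strictly increasing
    in every present gene's expression.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    genes = list(genes)
    present = [g for g in genes if g in expr.values.index]
    if not present:
        raise ValueError("none of the signature genes are present")
    if len(present) < len(genes):
        logger.info("signature: %d/%d genes missing", len(genes) - len(present),
                    len(genes))
    logs = np.log(expr.values.loc[present] + epsilon)
    score = np.exp(logs.sum(axis=0) / exponent)
    score.attrs["exponent"] = exponent
    score.attrs["n_genes_used"] = len(present)
    return score.rename("sqrt_product_signature")


def classify_tumor_role(cluster_labels: pd.Series,
                        role_map: dict[str, str] | None = None,
                        sample_key: pd.Series | None = None) -> pd.DataFrame:
    """Per-sample fractions of pro-tumour / anti-tumour / other neutrophils.

    ``cluster_labels`` maps cells to annotated cluster labels; labels absent
    from the role map fall to "other" with a warning.  Without per-cell
    sample ids a single overall row is returned.
    """
    role_map = dict(DEFAULT_ROLE_MAP if role_map is None else role_map)
    unmapped = sorted(set(cluster_labels.dropna()) - set(role_map))
    if unmapped:
        warnings.warn(f"labels without a role mapping treated as 'other': {unmapped}")
    roles = cluster_labels.map(lambda l: role_map.get(l, "other"))
    if sample_key is None:
        sample_key = pd.Series("all", index=cluster_labels.index)
    table = (
        pd.crosstab(sample_key, roles)
        .reindex(columns=list(ROLES), fill_value=0)
        .astype(float)
    )
    fracs = table.div(table.sum(axis=1), axis=0)
    fracs.index.name = "sample"
    return fracs


def load_marker_panel(path: str | Path) -> dict[str, tuple[str, ...]]:
    data = yaml.safe_load(Path(path).read_text())
    return {name: tuple(genes) for name, genes in data.items()}


def load_role_map(path: str | Path) -> dict[str, str]:
    return dict(yaml.safe_load(Path(path).read_text()))
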