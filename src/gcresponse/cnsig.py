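"""Copy-number signatures: context encoding, NMF extraction, catalog matching.

Segments are summarised into a 24-bin context matrix (6 total-copy-number
classes x 4 length classes; total-CN only, since shallow ~1x WGS provides no
allele-specific calls).  Signatures are extracted by KL-divergence NMF with
multiplicative updates and random restarts — the standard formulation for
count catalogues — then matched to a bundled catalog by cosine similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from sklearn.decomposition import NMF

from ._utils import child_seed, cosine
from .io import SegmentProfile
from .synthetic import CN_CLASSES, CONTEXT_LABELS, LENGTH_CLASSES, default_cn_catalog

__all__ = [
    "ContextMatrix",
    "CNSignatureSet",
    "encode_cn_contexts",
    "extract_signatures",
    "match_to_catalog",
    "compare_exposures",
    "load_catalog",
    "default_cn_catalog",
]

# left-closed, right-open length bins in bp; lengths are end - start + 1
_LENGTH_EDGES = (100_000, 1_000_000, 10_000_000)
_CN_UPPER = (0, 1, 2, 4, 8)  # upper bound (inclusive) of each class but the last


def _cn_class_index(total_cn: int) -> int:
    for i, ub in enumerate(_CN_UPPER):
        if total_cn <= ub:
            return i
    return len(_CN_UPPER)


def _length_class_index(length: int) -> int:
    for i, edge in enumerate(_LENGTH_EDGES):
        if length < edge:
            return i
    return len(_LENGTH_EDGES)


def classify_segment(total_cn: int, length: int) -> str:
    """Context label of a single segment (the per-segment bin rule)."""
    if total_cn < 0:
        raise ValueError("negative total copy number")
    return f"CN{CN_CLASSES[_cn_class_index(total_cn)]}:{LENGTH_CLASSES[_length_class_index(length)]}"


@dataclass
class ContextMatrix:
    counts: pd.DataFrame  # samples x 24 context bins (fixed, ordered labels)

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(CONTEXT_LABELS):
            raise ValueError("context columns must be the fixed 24-bin labels")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("context counts must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class CNSignatureSet:
    spectra: pd.DataFrame     # K x 24, rows on the simplex
    exposures: pd.DataFrame   # samples x K, non-negative
    assignments: dict[str, tuple[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = self.spectra.to_numpy()
        if (s < 0).any() or (self.exposures.to_numpy() < 0).any():
            raise ValueError("spectra and exposures must be non-negative")
        if not np.allclose(s.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("spectrum rows must sum to 1")


def encode_cn_contexts(profiles: Sequence[SegmentProfile]) -> ContextMatrix:
    """Count each sample's segments into the 24 (CN class, length class) bins."""
    label_idx = {lab: i for i, lab in enumerate(CONTEXT_LABELS)}
    counts = np.zeros((len(profiles), len(CONTEXT_LABELS)), dtype=int)
    for i, prof in enumerate(profiles):
        seg = prof.segments
        lengths = (seg["end"] - seg["start"] + 1).to_numpy()
        for cn, length in zip(seg["total_cn"].to_numpy(), lengths):
            counts[i, label_idx[classify_segment(int(cn), int(length))]] += 1
    return ContextMatrix(
        counts=pd.DataFrame(counts, index=[p.sample_id for p in profiles],
                            columns=list(CONTEXT_LABELS))
    )


def extract_signatures(c: ContextMatrix, rank: int = 2, n_restarts: int = 30,
                       seed: int = 0, max_iter: int = 2000,
                       tol: float = 1e-6) -> CNSignatureSet:
    """KL-divergence NMF of the context matrix, best of ``n_restarts``.

    Spectra rows are renormalised to the simplex with exposures rescaled
    compensatingly, so exposures are in segment-count units.  Deterministic
    given the seed (restart r uses a derived child seed).
    """
    x = c.counts.to_numpy(dtype=float)
    if not x.any():
        raise ValueError("context matrix is all zero")
    if rank < 1 or rank > min(x.shape[0], x.shape[1]):
        raise ValueError(f"rank {rank} outside [1, {min(x.shape)}]")
    best = None
    for r in range(n_restarts):
        model = NMF(
            n_components=rank,
            init="random",
            solver="mu",
            beta_loss="kullback-leibler",
            max_iter=max_iter,
            tol=tol,
            random_state=child_seed(seed, f"nmf_restart_{r}"),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w = model.fit_transform(x)
        if best is None or model.reconstruction_err_ < best[0]:
            best = (model.reconstruction_err_, w, model.components_)
    _, w, h = best
    row_sums = h.sum(axis=1)
    row_sums[row_sums == 0] = 1.0
    spectra = h / row_sums[:, None]
    exposures = w * row_sums[None, :]
    names = [f"Sig{i + 1}" for i in range(rank)]
    return CNSignatureSet(
        spectra=pd.DataFrame(spectra, index=names, columns=list(CONTEXT_LABELS)),
        exposures=pd.DataFrame(exposures, index=c.sample_ids, columns=names),
    )


def match_to_catalog(s: CNSignatureSet, catalog: pd.DataFrame | None = None) -> CNSignatureSet:
    """Assign each extracted spectrum its argmax-cosine catalog entry.

    Ties break by catalog order with a warning; an all-orthogonal spectrum is
    still assigned (similarity 0) with a warning.
    """
    if catalog is None:
        catalog = default_cn_catalog()
    if list(catalog.columns) != list(s.spectra.columns):
        raise ValueError("catalog bins do not match the spectra's 24-bin scheme")
    assignments = {}
    for name, spec in s.spectra.iterrows():
        sims = np.array([cosine(spec.to_numpy(), catalog.loc[cat].to_numpy())
                         for cat in catalog.index])
        best = int(np.argmax(sims))
        if (sims == sims[best]).sum() > 1:
            warnings.warn(f"{name}: cosine tie broken by catalog order")
        if sims[best] == 0.0:
            warnings.warn(f"{name}: orthogonal to every catalog entry")
        assignments[name] = (str(catalog.index[best]), float(sims[best]))
    return CNSignatureSet(spectra=s.spectra, exposures=s.exposures,
                          assignments=assignments)


def compare_exposures(s: CNSignatureSet, labels: pd.Series) -> pd.DataFrame:
    """Per-signature two-sided Mann-Whitney U between two label groups.

    Exact enumeration when both arms have <= 8 samples, tie-corrected normal
    approximation otherwise.
    """
    labels = labels.reindex(s.exposures.index).dropna()
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    a_ids = labels[labels == groups[0]].index
    b_ids = labels[labels == groups[1]].index
    rows = []
    for sig in s.exposures.columns:
        a = s.exposures.loc[a_ids, sig].to_numpy()
        b = s.exposures.loc[b_ids, sig].to_numpy()
        method = "exact" if max(len(a), len(b)) <= 8 else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        rows.append({"signature": sig, "U": float(res.statistic),
                     "p": float(res.pvalue), "method": method,
                     f"median_{groups[0]}": float(np.median(a)),
                     f"median_{groups[1]}": float(np.median(b))})
    return pd.DataFrame(rows).set_index("signature")


def load_catalog(path: str | Path) -> pd.DataFrame:
    """Load a catalog of named 24-bin spectra from TSV or YAML."""
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text())
        df = pd.DataFrame.from_dict(data, orient="index")
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(CONTEXT_LABELS) - set(df.columns)
    if missing:
        raise ValueError(f"catalog missing context bins: {sorted(missing)[:4]}")
    return df[list(CONTEXT_LABELS)].astype(float)
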