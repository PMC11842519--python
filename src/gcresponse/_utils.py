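"""Shared numeric helpers: named random streams, cosine similarity, rank AUC."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream", "child_seed", "cosine", "rank_auc"]


def child_seed(master_seed: int, name: str) -> int:
    """Derive a deterministic 31-bit child seed for a named component.

    All randomness in the package flows from a single master seed through
    these named streams so each pipeline stage is independently reproducible.
    """
    tag = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    mixed = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, tag])
    return int(mixed.generate_state(1, np.uint32)[0]) & 0x7FFFFFFF


def stream(master_seed: int, name: str) -> np.random.Generator:
    """A numpy Generator for the named component of a run."""
    return np.random.default_rng(child_seed(master_seed, name))


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity of two 1-D vectors; 0.0 if either has zero norm."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the rank (Mann-Whitney) statistic, ties credited 0.5.

    Equals the probability that a random positive outranks a random
    negative, with ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("rank_auc requires both classes present")
    # midranks handle ties exactly
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(len(scores), dtype=float)
    sorted_scores = scores[order]
    i = 0
    while i < len(scores):
        j = i
        while j + 1 < len(scores) and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    r_pos = ranks[labels].sum()
    u = r_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
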