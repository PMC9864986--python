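"""Conflict measures between bodies of evidence.

Jousselme distance (mass vectors compared under the Jaccard-overlap matrix of
focal subsets), per-evidence similarity scores derived from it, and cosine
similarity of mass vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError, UnsupportedInputError, ValidationError
from .mass_core import Frame, MassFunction, _check_same_frame

__all__ = [
    "jaccard_matrix",
    "jousselme_distance",
    "SimilarityScores",
    "similarity_scores",
    "cosine_similarity",
    "SIM_NORMALIZATIONS",
]

#: The dense (2^n - 1)^2 Jaccard matrix is only materialized for small frames.
MAX_MATRIX_FRAME_SIZE = 10

SIM_NORMALIZATIONS = ("sum", "mean")


@lru_cache(maxsize=32)
def _jaccard_matrix_for_size(n: int) -> np.ndarray:
    masks = np.arange(1, 1 << n, dtype=np.uint32)
    inter = np.bitwise_count(masks[:, None] & masks[None, :])
    union = np.bitwise_count(masks[:, None] | masks[None, :])
    return inter.astype(float) / union.astype(float)


def jaccard_matrix(frame: Frame) -> np.ndarray:
    """Matrix D with D[i, j] = |Ai n Aj| / |Ai u Aj| over non-empty subsets.

    Row/column index equals bitmask - 1 (the order of
    :meth:`MassFunction.to_vector`). Symmetric, unit diagonal, entries in
    [0, 1].
    """
    if frame.n > MAX_MATRIX_FRAME_SIZE:
        raise UnsupportedInputError(
            f"Jaccard matrix would be ({2**frame.n - 1})^2; frames larger than "
            f"{MAX_MATRIX_FRAME_SIZE} are not supported"
        )
    return _jaccard_matrix_for_size(frame.n)


def jousselme_distance(m1: MassFunction, m2: MassFunction) -> float:
    """Jousselme distance sqrt(0.5 * (v1-v2) D (v1-v2)^T) in [0, 1].

    For singleton-only (Bayesian) BPAs D reduces to the identity on the
    occupied coordinates and the distance collapses to ||m1 - m2|| / sqrt(2).
    """
    _check_same_frame(m1, m2)
    if m1.is_bayesian and m2.is_bayesian:
        diff = m1.singleton_array() - m2.singleton_array()
        return float(np.sqrt(0.5 * diff @ diff))
    d = jaccard_matrix(m1.frame)
    diff = m1.to_vector() - m2.to_vector()
    quad = float(diff @ d @ diff)
    return float(np.sqrt(0.5 * max(quad, 0.0)))


@dataclass(frozen=True)
class SimilarityScores:
    """Per-evidence similarity: raw sums of (1 - distance) and a normalization.

    ``raw[i]`` lies in [0, N-1] for N evidences. The default ``sum``
    normalization rescales the raw scores so they total N-1; ``mean`` divides
    each by N-1.
    """

    raw: np.ndarray
    normalized: np.ndarray
    normalization: str

    def __len__(self) -> int:
        return len(self.raw)


def similarity_scores(
    evidence: Sequence[MassFunction], normalization: str = "sum"
) -> SimilarityScores:
    """Sim(mi) = sum over j != i of (1 - JBPA(mi, mj)), plus a normalization."""
    evidence = list(evidence)
    if len(evidence) < 2:
        raise ValidationError("similarity scores need at least 2 evidences")
    if normalization not in SIM_NORMALIZATIONS:
        raise ValidationError(
            f"unknown similarity normalization {normalization!r}; valid: {SIM_NORMALIZATIONS}"
        )
    for m in evidence[1:]:
        _check_same_frame(evidence[0], m)
    n = len(evidence)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = jousselme_distance(evidence[i], evidence[j])
    raw = (1.0 - dist).sum(axis=1) - 1.0  # drop the diagonal self-term
    raw = np.clip(raw, 0.0, None)
    if normalization == "sum":
        total = raw.sum()
        if total > 0:
            normalized = raw * (n - 1) / total
        else:  # all pairwise distances are 1: no information to rank on
            normalized = np.full(n, (n - 1) / n)
    else:
        normalized = raw / (n - 1)
    return SimilarityScores(raw=raw, normalized=normalized, normalization=normalization)


def cosine_similarity(m1: MassFunction, m2: MassFunction) -> float:
    """Cosine of the angle between the two mass vectors over all subsets."""
    _check_same_frame(m1, m2)
    v1, v2 = m1.to_vector(), m2.to_vector()
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise DegenerateInputError("cosine similarity is undefined for an all-zero mass vector")
    return float(v1 @ v2 / (n1 * n2))
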