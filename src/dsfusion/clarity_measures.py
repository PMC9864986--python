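"""Clarity (anti-fuzziness) of evidence: distance to the uniform reference.

The maximum-entropy reference assigns 1/n to every singleton. A BPA far from
it is sharp ("clear"); a BPA at it is maximally fuzzy. Belief entropies are
provided as diagnostics for BPAs with compound focal sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import UndefinedEntropyError, UnsupportedInputError, ValidationError
from .mass_core import Frame, MassFunction, belief

__all__ = [
    "uniform_reference",
    "wasserstein_to_uniform",
    "ClarityScores",
    "clarity_scores",
    "hohle_entropy",
    "deng_entropy",
    "CLARITY_METRICS",
]

#: Supported distance-to-uniform metrics. ``index_w1`` treats classes as
#: unit-spaced points in frame order and is the 1-D Wasserstein-1 distance.
CLARITY_METRICS = ("index_w1", "total_variation", "euclidean")

_ALL_UNIFORM_EPS = 1e-12


def uniform_reference(frame: Frame) -> MassFunction:
    """The maximum-entropy BPA: mass 1/n on every singleton."""
    return MassFunction(frame, {1 << i: 1.0 / frame.n for i in range(frame.n)})


def _singleton_probs(m: MassFunction) -> np.ndarray:
    if not m.is_bayesian:
        raise UnsupportedInputError(
            "distance-to-uniform clarity is defined for singleton-only BPAs; "
            "use hohle_entropy/deng_entropy for compound focal sets"
        )
    return m.singleton_array()


def wasserstein_to_uniform(m: MassFunction, metric: str = "index_w1") -> float:
    """Distance from a singleton-only BPA to the uniform reference.

    ``index_w1``
        Wasserstein-1 with classes as unit-spaced points in frame order:
        the sum of absolute cumulative-distribution differences.
    ``total_variation``
        0.5 * sum |m(theta) - 1/n|.
    ``euclidean``
        L2 norm of the difference vector.
    """
    if metric not in CLARITY_METRICS:
        raise ValidationError(f"unknown clarity metric {metric!r}; valid: {CLARITY_METRICS}")
    p = _singleton_probs(m)
    u = 1.0 / m.frame.n
    diff = p - u
    if metric == "index_w1":
        return float(np.abs(np.cumsum(diff)).sum())
    if metric == "total_variation":
        return float(0.5 * np.abs(diff).sum())
    return float(np.linalg.norm(diff))


@dataclass(frozen=True)
class ClarityScores:
    """Per-evidence distance-to-uniform, raw and normalized to sum 1."""

    raw: np.ndarray
    normalized: np.ndarray
    metric: str

    def __len__(self) -> int:
        return len(self.raw)


def clarity_scores(evidence: Sequence[MassFunction], metric: str = "index_w1") -> ClarityScores:
    """Raw distances to uniform plus normalized shares (raw / sum raw).

    If every evidence is exactly uniform the shares default to 1/N each.
    """
    evidence = list(evidence)
    if not evidence:
        raise ValidationError("clarity scores need at least 1 evidence")
    raw = np.array([wasserstein_to_uniform(m, metric) for m in evidence])
    total = raw.sum()
    if total <= _ALL_UNIFORM_EPS:
        normalized = np.full(len(evidence), 1.0 / len(evidence))
    else:
        normalized = raw / total
    return ClarityScores(raw=raw, normalized=normalized, metric=metric)


def hohle_entropy(m: MassFunction) -> float:
    """-sum m(A) log2 Bel(A) over focal sets, in bits."""
    out = 0.0
    for mask, value in m.items():
        bel = belief(m, mask)
        if bel <= 0:
            raise UndefinedEntropyError(
                f"belief of focal set {m.frame.format_subset(mask)!r} is zero"
            )
        out -= value * np.log2(bel)
    return float(out)


def deng_entropy(m: MassFunction) -> float:
    """-sum m(A) log2( m(A) / (2^|A| - 1) ), in bits.

    Reduces to Shannon entropy when every focal set is a singleton.
    """
    out = 0.0
    for mask, value in m.items():
        if value <= 0:
            continue
        cardinality = int(mask).bit_count()
        out -= value * np.log2(value / (2**cardinality - 1))
    return float(out)
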