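"""Adaptive evidence weighting and trust-discount BPA reallocation.

The proposed weight blends per-evidence similarity (low conflict) and clarity
(low fuzziness), damping the clarity term exponentially when the two disagree
so that a sharp but dissenting evidence cannot dominate. Baseline schemes
(similarity only, clarity only, product, arithmetic mean) are provided for
comparison. The resulting weight W discounts each BPA, moving mass from each
class toward the others in proportion to 1 - W.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .clarity_measures import ClarityScores
from .conflict_measures import SimilarityScores
from .errors import DegenerateInputError, UnsupportedInputError, ValidationError
from .mass_core import MassFunction

__all__ = [
    "WeightVector",
    "combined_weight",
    "baseline_weight",
    "trust_discount",
    "discount_all",
    "WEIGHT_SCHEMES",
    "EXPONENT_MODES",
    "DIVISOR_MODES",
]

WEIGHT_SCHEMES = ("proposed", "conflict_only", "clarity_only", "product", "arithmetic_mean")
EXPONENT_MODES = ("damping", "amplifying")
DIVISOR_MODES = ("frame_minus_one", "literal_two")

_RANGE_TOL = 1e-9


@dataclass(frozen=True)
class WeightVector:
    """Per-evidence trust weights in [0, 1] plus the scheme that produced them."""

    values: np.ndarray
    scheme: str

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)


def _as_unit_interval(values: np.ndarray, what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if np.any(values < -_RANGE_TOL) or np.any(values > 1 + _RANGE_TOL):
        raise ValidationError(f"{what} values must lie in [0, 1], got {values!r}")
    return np.clip(values, 0.0, 1.0)


def _scores(sim_or_array, cls) -> np.ndarray:
    if isinstance(sim_or_array, cls):
        return sim_or_array.normalized
    return np.asarray(sim_or_array, dtype=float)


def combined_weight(
    sim: SimilarityScores | np.ndarray,
    clar: ClarityScores | np.ndarray,
    exponent_mode: str = "damping",
) -> WeightVector:
    """W = 0.5 * (Sim + Clar * exp(-|Clar - Sim|)) per evidence (damping mode).

    The exponent |(1 - Sim) + Clar - 1| equals |Clar - Sim|: the clarity
    contribution is shrunk exactly when clarity and similarity disagree, so a
    sharp evidence that conflicts with the majority cannot collect a large
    weight. ``amplifying`` multiplies by exp(+|Clar - Sim|) instead
    (sensitivity analysis only; results are clipped into [0, 1]).

    Normalized scores are expected (each in [0, 1]).
    """
    if exponent_mode not in EXPONENT_MODES:
        raise ValidationError(f"unknown exponent mode {exponent_mode!r}; valid: {EXPONENT_MODES}")
    s = _as_unit_interval(_scores(sim, SimilarityScores), "similarity")
    c = _as_unit_interval(_scores(clar, ClarityScores), "clarity")
    if s.shape != c.shape:
        raise ValidationError(f"similarity and clarity cover different evidence counts: {s.shape} vs {c.shape}")
    gap = np.abs(c - s)
    factor = np.exp(-gap) if exponent_mode == "damping" else np.exp(gap)
    w = 0.5 * (s + c * factor)
    return WeightVector(values=np.clip(w, 0.0, 1.0), scheme="proposed")


def baseline_weight(
    sim: SimilarityScores | np.ndarray,
    clar: ClarityScores | np.ndarray,
    scheme: str,
) -> WeightVector:
    """Reference weighting schemes the adaptive weight is compared against."""
    s = _as_unit_interval(_scores(sim, SimilarityScores), "similarity")
    c = _as_unit_interval(_scores(clar, ClarityScores), "clarity")
    if s.shape != c.shape:
        raise ValidationError(f"similarity and clarity cover different evidence counts: {s.shape} vs {c.shape}")
    if scheme == "conflict_only":
        w = s
    elif scheme == "clarity_only":
        w = c
    elif scheme == "product":
        raw = s * c
        peak = raw.max()
        if peak <= 0:
            raise DegenerateInputError("product weights are all zero; cannot rescale to max 1")
        w = raw / peak
    elif scheme == "arithmetic_mean":
        w = 0.5 * (s + c)
    elif scheme == "proposed":
        return combined_weight(sim, clar)
    else:
        raise ValidationError(f"unknown weight scheme {scheme!r}; valid: {WEIGHT_SCHEMES}")
    return WeightVector(values=np.clip(w, 0.0, 1.0), scheme=scheme)


def trust_discount(
    m: MassFunction, w: float, divisor_mode: str = "frame_minus_one"
) -> MassFunction:
    """Reallocate a singleton-only BPA toward its complements by trust W.

    new(theta) = m(theta) * W + ((1 - W) / c) * (1 - m(theta))

    With c = n - 1 (default) the output sums to 1 identically; the literal
    c = 2 variant is renormalized afterwards (harmless under Dempster's
    scale cancellation).
    """
    if divisor_mode not in DIVISOR_MODES:
        raise ValidationError(f"unknown divisor mode {divisor_mode!r}; valid: {DIVISOR_MODES}")
    if not m.is_bayesian:
        raise UnsupportedInputError("trust discount is defined for singleton-only BPAs")
    w = float(w)
    if not 0.0 - _RANGE_TOL <= w <= 1.0 + _RANGE_TOL:
        raise ValidationError(f"trust weight must lie in [0, 1], got {w}")
    w = min(max(w, 0.0), 1.0)
    n = m.frame.n
    if n == 1:
        return m
    divisor = (n - 1) if divisor_mode == "frame_minus_one" else 2
    p = m.singleton_array()
    new = p * w + (1.0 - w) / divisor * (1.0 - p)
    if divisor_mode == "literal_two":
        new = new / new.sum()  # c = 2 is not self-normalizing for n != 3
    masses = {1 << i: float(v) for i, v in enumerate(new) if v > 0}
    return MassFunction(m.frame, masses)


def discount_all(
    evidence: Sequence[MassFunction],
    weights: WeightVector | Sequence[float],
    divisor_mode: str = "frame_minus_one",
) -> list[MassFunction]:
    """Element-wise :func:`trust_discount` over matched evidence/weight lists."""
    evidence = list(evidence)
    values = weights.values if isinstance(weights, WeightVector) else np.asarray(weights, dtype=float)
    if len(evidence) != len(values):
        raise ValidationError(
            f"got {len(evidence)} evidences but {len(values)} weights"
        )
    return [trust_discount(m, w, divisor_mode) for m, w in zip(evidence, values)]
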