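"""Frames of discernment, mass functions (BPAs) and Dempster's combination rule.

Subsets of a frame are represented as integer bitmasks over the frame's fixed
label order: bit ``i`` set means the ``i``-th label is in the subset. The empty
set is mask 0 and never carries mass.
"""

from __future__ import annotations

import csv
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateInputError,
    TotalConflictError,
    ValidationError,
)

__all__ = [
    "Frame",
    "MassFunction",
    "CombinationResult",
    "make_mass",
    "belief",
    "dempster_combine",
    "combine_all",
    "vacuous_mass",
    "read_bpa_csv",
    "write_bpa_csv",
]

#: Mass-conservation tolerance for constructed/fused BPAs.
MASS_TOL = 1e-9
#: Combined masses below this are pruned (then renormalized) for hygiene.
PRUNE_EPS = 1e-15
#: k above 1 - this threshold counts as total conflict.
TOTAL_CONFLICT_EPS = 1e-12
#: Bitmask representation caps the frame size.
MAX_FRAME_SIZE = 20

#: Separator used for focal sets in the BPA CSV dialect, e.g. ``A|B``.
FOCAL_SET_SEPARATOR = "|"


@dataclass(frozen=True)
class Frame:
    """Ordered finite set of mutually exclusive hypotheses.

    The label order is fixed and meaningful: it determines bit positions of
    subsets and the singleton index positions used by the clarity measures.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) == 0:
            raise ValidationError("a frame needs at least one hypothesis")
        if len(labels) > MAX_FRAME_SIZE:
            raise ValidationError(
                f"frame size {len(labels)} exceeds the bitmask cap of {MAX_FRAME_SIZE}"
            )
        if any(label == "" for label in labels):
            raise ValidationError("frame labels must be non-empty strings")
        if len(set(labels)) != len(labels):
            raise ValidationError(f"frame labels must be unique, got {labels!r}")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def full_mask(self) -> int:
        return (1 << self.n) - 1

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValidationError(f"label {label!r} is not in frame {self.labels!r}") from None

    def singleton(self, label: str) -> int:
        """Bitmask of the singleton subset {label}."""
        return 1 << self.index(label)

    def subset(self, spec) -> int:
        """Coerce a subset specification to a bitmask.

        Accepts an int bitmask, a label, a ``'|'``-joined label string, or an
        iterable of labels.
        """
        if isinstance(spec, (int, np.integer)):
            mask = int(spec)
            if mask < 0 or mask > self.full_mask:
                raise ValidationError(f"bitmask {mask} out of range for frame of size {self.n}")
            return mask
        if isinstance(spec, str):
            parts = spec.split(FOCAL_SET_SEPARATOR) if FOCAL_SET_SEPARATOR in spec else [spec]
            spec = [p.strip() for p in parts]
        if isinstance(spec, Iterable):
            mask = 0
            for label in spec:
                mask |= self.singleton(label)
            return mask
        raise ValidationError(f"cannot interpret {spec!r} as a subset of the frame")

    def labels_of(self, mask: int) -> tuple[str, ...]:
        return tuple(lab for i, lab in enumerate(self.labels) if mask >> i & 1)

    def format_subset(self, mask: int) -> str:
        return FOCAL_SET_SEPARATOR.join(self.labels_of(mask))


@dataclass(frozen=True)
class MassFunction:
    """A basic probability assignment: masses on non-empty subsets summing to 1.

    Instances are built by :func:`make_mass` (or the combination operators),
    which enforce the invariants; the raw constructor expects a clean dict of
    strictly positive masses keyed by bitmask.
    """

    frame: Frame
    masses: Mapping[int, float]

    def mass(self, spec) -> float:
        return self.masses.get(self.frame.subset(spec), 0.0)

    def focal_sets(self) -> tuple[int, ...]:
        return tuple(self.masses)

    def items(self):
        return self.masses.items()

    @property
    def is_bayesian(self) -> bool:
        """True when every focal set is a singleton."""
        return all(mask & (mask - 1) == 0 for mask in self.masses)

    def singleton_array(self) -> np.ndarray:
        """Masses on singletons in frame order (compound masses excluded)."""
        out = np.zeros(self.frame.n)
        for i in range(self.frame.n):
            out[i] = self.masses.get(1 << i, 0.0)
        return out

    def to_vector(self) -> np.ndarray:
        """Mass vector over all non-empty subsets, index = bitmask - 1."""
        out = np.zeros((1 << self.frame.n) - 1)
        for mask, m in self.masses.items():
            out[mask - 1] = m
        return out

    def belief(self, spec) -> float:
        return belief(self, spec)

    def total(self) -> float:
        return float(sum(self.masses.values()))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        body = ", ".join(
            f"{self.frame.format_subset(mask)}: {m:.4g}" for mask, m in sorted(self.masses.items())
        )
        return f"MassFunction({{{body}}})"


@dataclass(frozen=True)
class CombinationResult:
    """Outcome of Dempster combination: the fused BPA and the conflict k."""

    fused: MassFunction
    conflict_k: float


def make_mass(frame: Frame, assignments: Mapping, normalize: bool = False) -> MassFunction:
    """Build a validated :class:`MassFunction`.

    ``assignments`` maps subset specs (see :meth:`Frame.subset`) to
    non-negative masses. With ``normalize`` the masses are rescaled to sum to
    1; otherwise they must already sum to 1 within ``MASS_TOL``.
    """
    masses: dict[int, float] = {}
    for spec, value in assignments.items():
        mask = frame.subset(spec)
        if mask == 0:
            raise ValidationError("the empty set cannot carry mass (m(emptyset) = 0)")
        value = float(value)
        if value < 0:
            raise ValidationError(
                f"mass of {frame.format_subset(mask)!r} is negative ({value})"
            )
        if not np.isfinite(value):
            raise ValidationError(f"mass of {frame.format_subset(mask)!r} is not finite")
        masses[mask] = masses.get(mask, 0.0) + value

    total = sum(masses.values())
    if normalize:
        if total <= 0:
            raise DegenerateInputError("cannot normalize an all-zero mass assignment")
        masses = {mask: m / total for mask, m in masses.items() if m > 0}
    else:
        if abs(total - 1.0) > MASS_TOL:
            raise ValidationError(f"masses must sum to 1 (got {total!r}); pass normalize=True")
        masses = {mask: m for mask, m in masses.items() if m > 0}
    return MassFunction(frame, masses)


def vacuous_mass(frame: Frame) -> MassFunction:
    """The vacuous BPA: all mass on the full frame."""
    return MassFunction(frame, {frame.full_mask: 1.0})


def belief(m: MassFunction, spec) -> float:
    """Bel(A) = sum of masses of non-empty subsets of A."""
    a = m.frame.subset(spec)
    return float(sum(v for mask, v in m.masses.items() if mask & ~a == 0))


def _check_same_frame(m1: MassFunction, m2: MassFunction) -> None:
    if m1.frame != m2.frame:
        raise ValidationError(
            f"mass functions live on different frames: {m1.frame.labels!r} vs {m2.frame.labels!r}"
        )


def dempster_combine(m1: MassFunction, m2: MassFunction) -> CombinationResult:
    """Dempster's rule: normalized product of masses over subset intersections.

    k, the conflict coefficient, is the total product mass landing on the
    empty set; the fused masses are divided by 1 - k.
    """
    _check_same_frame(m1, m2)
    fused: dict[int, float] = {}
    k = 0.0
    for a, ma in m1.masses.items():
        for b, mb in m2.masses.items():
            inter = a & b
            prod = ma * mb
            if inter == 0:
                k += prod
            else:
                fused[inter] = fused.get(inter, 0.0) + prod
    # k relative to the total product mass, so per-evidence scales cancel
    # (for proper BPAs the totals are 1 and this is k itself)
    k /= m1.total() * m2.total()
    if k > 1.0 - TOTAL_CONFLICT_EPS:
        raise TotalConflictError(
            f"total conflict (k = {k!r}) between {m1!r} and {m2!r}: Dempster's rule is undefined"
        )
    total = sum(fused.values())
    fused = {mask: m / total for mask, m in fused.items() if m / total > PRUNE_EPS}
    total = sum(fused.values())
    fused = {mask: m / total for mask, m in fused.items()}
    return CombinationResult(MassFunction(m1.frame, fused), float(k))


def combine_all(evidence: Sequence[MassFunction]) -> CombinationResult:
    """Left fold of :func:`dempster_combine` over the evidence list.

    Reports the conflict coefficient of the final pairwise step (0 for a
    single evidence). The fused masses are order-independent.
    """
    evidence = list(evidence)
    if not evidence:
        raise ValidationError("combine_all needs at least one mass function")
    for m in evidence[1:]:
        _check_same_frame(evidence[0], m)
    if len(evidence) == 1:
        return CombinationResult(evidence[0], 0.0)
    result = dempster_combine(evidence[0], evidence[1])
    for m in evidence[2:]:
        result = dempster_combine(result.fused, m)
    return result


# ---------------------------------------------------------------------------
# BPA CSV dialect: header `focal_set,mass`, focal sets as `|`-joined labels.
# ---------------------------------------------------------------------------

def read_bpa_csv(path, frame: Frame | None = None, normalize: bool = False) -> MassFunction:
    """Read a BPA from CSV (``focal_set,mass``).

    Without an explicit frame, the labels are inferred in order of first
    appearance across focal sets.
    """
    rows: list[tuple[str, float]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or {"focal_set", "mass"} - set(reader.fieldnames):
            raise ValidationError(f"{path}: expected header 'focal_set,mass'")
        for lineno, row in enumerate(reader, start=2):
            try:
                rows.append((row["focal_set"], float(row["mass"])))
            except (TypeError, ValueError):
                raise ValidationError(f"{path}:{lineno}: malformed mass value {row['mass']!r}") from None
    if frame is None:
        seen: dict[str, None] = {}
        for focal, _ in rows:
            for label in focal.split(FOCAL_SET_SEPARATOR):
                seen.setdefault(label.strip(), None)
        frame = Frame(tuple(seen))
    assignments: dict[int, float] = {}
    for focal, m in rows:
        mask = frame.subset(focal)
        assignments[mask] = assignments.get(mask, 0.0) + m
    return make_mass(frame, assignments, normalize=normalize)


def write_bpa_csv(m: MassFunction, path) -> None:
    """Write a BPA in the ``focal_set,mass`` CSV dialect."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["focal_set", "mass"])
        for mask in sorted(m.masses):
            writer.writerow([m.frame.format_subset(mask), repr(m.masses[mask])])
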