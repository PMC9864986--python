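"""Synthetic fixtures: wearable-like labeled feature tables and canned
conflict/fuzziness evidence scenarios.

The default prototype table mimics a five-activity wearable setup (mean
accelerometer magnitude, gyroscope magnitude, and heart rate per activity) so
the whole pipeline can be exercised without any external dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .mass_core import Frame, MassFunction, make_mass
from .activity_pipeline import PrototypeTable

__all__ = [
    "ACTIVITY_CLASSES",
    "ACTIVITY_SENSORS",
    "activity_prototypes",
    "WORKED_EXAMPLE_READING",
    "SyntheticConfig",
    "generate_dataset",
    "conflict_scenario",
]

#: Five activities ordered by intensity; the frame order is meaningful.
ACTIVITY_CLASSES = ("lying", "standing", "walking", "upstairs", "running")

#: One scalar feature per sensor: acceleration (m/s^2), angular velocity
#: (rad/s), heart rate (beats/min).
ACTIVITY_SENSORS = ("acc", "gyro", "bpm")

#: Per-sensor, per-class characteristic means (rows follow ACTIVITY_SENSORS).
_ACTIVITY_PROTOTYPE_VALUES = np.array(
    [
        [9.7987, 9.7676, 9.7433, 10.8592, 17.5110],
        [0.1868, 0.2126, 0.3021, 2.8186, 3.8023],
        [87.5275, 91.183, 103.4257, 120.4410609, 161.3601],
    ]
)

#: A walking window with high conflict between the ACC evidence (which leans
#: to "standing") and the GYRO/BPM evidences: (acc, gyro, bpm).
WORKED_EXAMPLE_READING = (9.7728, 0.39, 101.0)


def activity_prototypes() -> PrototypeTable:
    """The built-in five-activity, three-sensor prototype table."""
    return PrototypeTable(
        frame=Frame(ACTIVITY_CLASSES),
        sensors=ACTIVITY_SENSORS,
        values=_ACTIVITY_PROTOTYPE_VALUES.copy(),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Recipe for a labeled feature table.

    ``noise_sd`` is a scalar or one standard deviation per sensor, in sensor
    units. ``round_bpm`` optionally rounds any sensor literally named "bpm"
    to whole beats.
    """

    prototypes: PrototypeTable = field(default_factory=activity_prototypes)
    noise_sd: float | Sequence[float] = 0.1
    n_per_class: int = 100
    seed: int = 0
    round_bpm: bool = False

    def __post_init__(self) -> None:
        sd = np.atleast_1d(np.asarray(self.noise_sd, dtype=float))
        if sd.size == 1:
            sd = np.full(len(self.prototypes.sensors), float(sd[0]))
        if sd.size != len(self.prototypes.sensors):
            raise ValidationError(
                f"noise_sd has {sd.size} entries for {len(self.prototypes.sensors)} sensors"
            )
        if np.any(sd < 0):
            raise ValidationError("noise_sd must be >= 0")
        object.__setattr__(self, "noise_sd", tuple(float(x) for x in sd))
        if self.n_per_class < 1:
            raise ValidationError("n_per_class must be >= 1")


def generate_dataset(config: SyntheticConfig) -> pd.DataFrame:
    """Gaussian class-conditional feature table around the prototype means.

    Columns are the sensor names plus ``label``; rows are deterministically
    shuffled by the seed.
    """
    rng = np.random.default_rng(config.seed)
    proto = config.prototypes
    sd = np.asarray(config.noise_sd)
    frames = []
    for ci, cls in enumerate(proto.frame.labels):
        cols = {}
        for si, sensor in enumerate(proto.sensors):
            draws = rng.normal(proto.values[si, ci], sd[si], size=config.n_per_class)
            if config.round_bpm and sensor == "bpm":
                draws = np.round(draws)
            cols[sensor] = draws
        cols["label"] = cls
        frames.append(pd.DataFrame(cols))
    data = pd.concat(frames, ignore_index=True)
    order = rng.permutation(len(data))
    return data.iloc[order].reset_index(drop=True)


def conflict_scenario(
    n_classes: int,
    n_evidence: int,
    conflict_level: float,
    fuzziness_level: float,
    seed: int = 0,
    labels: Sequence[str] | None = None,
    target: str | None = None,
) -> list[MassFunction]:
    """A majority cluster of agreeing fuzzy BPAs plus one dissenting BPA.

    The ``n_evidence - 1`` majority BPAs put peak mass
    ``1 - fuzziness_level * (1 - 1/n)`` on the target class (so fuzziness 0 is
    certainty and fuzziness 1 is uniform), spreading the rest equally. The
    dissenter is the convex blend
    ``(1 - conflict_level) * majority + conflict_level * certainty-on-other``,
    the other class being drawn by the seeded RNG; conflict 0 makes all
    evidences identical.
    """
    if n_classes < 2:
        raise ValidationError("conflict_scenario needs at least 2 classes")
    if n_evidence < 2:
        raise ValidationError("conflict_scenario needs at least 2 evidences")
    for name, level in (("conflict_level", conflict_level), ("fuzziness_level", fuzziness_level)):
        if not 0.0 <= level <= 1.0:
            raise ValidationError(f"{name} must lie in [0, 1], got {level}")
    if labels is None:
        labels = tuple(f"C{i + 1}" for i in range(n_classes))
    frame = Frame(tuple(labels))
    if frame.n != n_classes:
        raise ValidationError(f"got {frame.n} labels for n_classes={n_classes}")
    target_idx = frame.index(target) if target is not None else 0

    rng = np.random.default_rng(seed)
    n = n_classes
    peak = 1.0 - fuzziness_level * (1.0 - 1.0 / n)
    majority = np.full(n, (1.0 - peak) / (n - 1))
    majority[target_idx] = peak

    others = [i for i in range(n) if i != target_idx]
    dissent_idx = int(rng.choice(others))
    point = np.zeros(n)
    point[dissent_idx] = 1.0
    dissenter = (1.0 - conflict_level) * majority + conflict_level * point

    def as_mass(p: np.ndarray) -> MassFunction:
        return make_mass(frame, {1 << i: float(v) for i, v in enumerate(p) if v > 0})

    return [as_mass(majority) for _ in range(n_evidence - 1)] + [as_mass(dissenter)]
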