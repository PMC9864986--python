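"""Decision-level multi-sensor fusion pipeline for activity recognition.

Per window: each sensor's scalar reading is turned into a singleton BPA by
inverse-distance to per-class prototype values; the BPAs are scored for
conflict (similarity) and fuzziness (clarity), weighted, trust-discounted,
and fused with Dempster's rule; the fused argmax is the decision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clarity_measures import CLARITY_METRICS, ClarityScores, clarity_scores
from .conflict_measures import SIM_NORMALIZATIONS, SimilarityScores, similarity_scores
from .errors import ConfigurationError, ValidationError
from .mass_core import CombinationResult, Frame, MassFunction, combine_all
from .weight_discount import (
    DIVISOR_MODES,
    EXPONENT_MODES,
    WEIGHT_SCHEMES,
    WeightVector,
    baseline_weight,
    combined_weight,
    discount_all,
)

__all__ = [
    "PipelineConfig",
    "PrototypeTable",
    "FusionResult",
    "EvaluationReport",
    "fit_prototypes",
    "generate_bpa",
    "classify",
    "evaluate",
    "kappa_from_confusion",
    "kappa_band",
]

logger = logging.getLogger(__name__)

#: Distances are clipped below at this value so a reading exactly on a
#: prototype yields (numerically) all mass on that class.
DISTANCE_EPS = 1e-12

#: ``ds`` = raw Dempster combination, no weighting/discounting.
CLASSIFY_SCHEMES = ("ds",) + WEIGHT_SCHEMES

#: Chance-corrected agreement bands (upper bound -> label).
KAPPA_BANDS = (
    (0.2, "slight"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "substantial"),
    (1.0, "almost perfect"),
)


@dataclass(frozen=True)
class PipelineConfig:
    """Vocabulary-checked knobs for the fusion pipeline.

    Defaults are the recommended configuration: the proposed adaptive weight,
    damping exponent, self-normalizing |frame|-1 discount divisor, unit-spaced
    Wasserstein-1 clarity, and similarity rescaled to sum to N-1.
    """

    weight_scheme: str = "proposed"
    clarity_metric: str = "index_w1"
    sim_normalization: str = "sum"
    exponent_mode: str = "damping"
    divisor_mode: str = "frame_minus_one"

    def __post_init__(self) -> None:
        for value, valid, what in (
            (self.weight_scheme, CLASSIFY_SCHEMES, "weight_scheme"),
            (self.clarity_metric, CLARITY_METRICS, "clarity_metric"),
            (self.sim_normalization, SIM_NORMALIZATIONS, "sim_normalization"),
            (self.exponent_mode, EXPONENT_MODES, "exponent_mode"),
            (self.divisor_mode, DIVISOR_MODES, "divisor_mode"),
        ):
            if value not in valid:
                raise ConfigurationError(f"unknown {what} {value!r}; valid: {valid}")


@dataclass(frozen=True)
class PrototypeTable:
    """Per-class characteristic value for each sensor (class means)."""

    frame: Frame
    sensors: tuple[str, ...]
    values: np.ndarray  # shape (n_sensors, n_classes)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "sensors", tuple(self.sensors))
        object.__setattr__(self, "values", values)
        if len(set(self.sensors)) != len(self.sensors):
            raise ValidationError(f"sensor names must be unique, got {self.sensors!r}")
        if values.shape != (len(self.sensors), self.frame.n):
            raise ValidationError(
                f"prototype values have shape {values.shape}, expected "
                f"({len(self.sensors)}, {self.frame.n})"
            )
        if not np.all(np.isfinite(values)):
            raise ValidationError("prototype values must be finite")

    def sensor_index(self, sensor: str) -> int:
        try:
            return self.sensors.index(sensor)
        except ValueError:
            raise ValidationError(f"unknown sensor {sensor!r}; have {self.sensors!r}") from None

    def row(self, sensor: str) -> np.ndarray:
        return self.values[self.sensor_index(sensor)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.sensors), columns=list(self.frame.labels))


@dataclass(frozen=True)
class FusionResult:
    """One classified window with all intermediates retained for reporting."""

    fused: MassFunction
    conflict_k: float
    decision: str
    weights: WeightVector | None
    bpas: tuple[MassFunction, ...]
    sim: SimilarityScores | None
    clar: ClarityScores | None
    config: PipelineConfig

    def fused_array(self) -> np.ndarray:
        return self.fused.singleton_array()


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion matrix plus the derived accuracy and agreement metrics."""

    confusion: pd.DataFrame  # rows = true class, columns = predicted class
    per_class_accuracy: pd.Series
    weighted_accuracy: float
    kappa: float
    kappa_band: str
    n: int


def fit_prototypes(
    dataset: pd.DataFrame,
    label_col: str = "label",
    class_order: Sequence[str] | None = None,
    sensors: Sequence[str] | None = None,
) -> PrototypeTable:
    """Per-class arithmetic mean of each sensor column.

    ``class_order`` fixes the frame order (default: sorted unique labels —
    pass an explicit order when the frame order is meaningful, e.g. activity
    intensity).
    """
    if label_col not in dataset.columns:
        raise ValidationError(f"dataset has no label column {label_col!r}")
    if len(dataset) == 0:
        raise ValidationError("dataset is empty")
    if sensors is None:
        sensors = [c for c in dataset.columns if c != label_col]
    if not sensors:
        raise ValidationError("dataset has no sensor columns")
    present = list(dict.fromkeys(dataset[label_col].astype(str)))
    if class_order is None:
        class_order = sorted(present)
    else:
        class_order = [str(c) for c in class_order]
        missing = set(class_order) - set(present)
        if missing:
            raise ValidationError(f"classes {sorted(missing)} have no rows in the dataset")
    frame = Frame(tuple(class_order))
    feats = dataset[list(sensors)].astype(float)
    if not np.all(np.isfinite(feats.to_numpy())):
        raise ValidationError("sensor features must be finite")
    grouped = feats.groupby(dataset[label_col].astype(str)).mean()
    values = grouped.reindex(class_order).to_numpy().T  # (n_sensors, n_classes)
    return PrototypeTable(frame=frame, sensors=tuple(sensors), values=values)


def _reading_value(reading, prototypes: PrototypeTable, sensor: str) -> float:
    if isinstance(reading, Mapping):
        if sensor not in reading:
            raise ValidationError(f"reading has no value for sensor {sensor!r}")
        value = reading[sensor]
    else:
        seq = list(reading)
        if len(seq) != len(prototypes.sensors):
            raise ValidationError(
                f"reading has {len(seq)} values but the prototype table has "
                f"{len(prototypes.sensors)} sensors"
            )
        value = seq[prototypes.sensor_index(sensor)]
    value = float(value)
    if not np.isfinite(value):
        raise ValidationError(f"reading for sensor {sensor!r} is not finite")
    return value


def generate_bpa(reading, prototypes: PrototypeTable, sensor: str) -> MassFunction:
    """Singleton BPA from one sensor reading by inverse-distance normalization.

    mass(c) proportional to 1 / |reading - prototype(sensor, c)|, distances
    clipped below at ``DISTANCE_EPS`` so an exact prototype hit concentrates
    the mass on that class.
    """
    value = _reading_value(reading, prototypes, sensor)
    dist = np.abs(value - prototypes.row(sensor))
    inv = 1.0 / np.clip(dist, DISTANCE_EPS, None)
    p = inv / inv.sum()
    return MassFunction(prototypes.frame, {1 << i: float(v) for i, v in enumerate(p) if v > 0})


def _decide(fused: MassFunction) -> str:
    p = fused.singleton_array()
    best = int(np.argmax(p))  # ties -> lowest frame index
    ties = np.flatnonzero(np.isclose(p, p[best], rtol=0, atol=1e-12))
    if len(ties) > 1:
        labels = [fused.frame.labels[i] for i in ties]
        logger.warning("decision tie between %s; choosing %r by frame order", labels, fused.frame.labels[best])
    return fused.frame.labels[best]


def classify(reading, prototypes: PrototypeTable, config: PipelineConfig | None = None) -> FusionResult:
    """Full fusion chain for one multi-sensor reading.

    BPAs per sensor -> similarity + clarity scores -> weights (per the
    configured scheme; ``ds`` skips weighting and discounting) -> trust
    discount -> Dempster combination -> argmax decision.
    """
    config = config or PipelineConfig()
    if len(prototypes.sensors) < 2:
        raise ValidationError("classification needs at least 2 sensors")
    bpas = tuple(generate_bpa(reading, prototypes, s) for s in prototypes.sensors)
    sim = clar = weights = None
    if config.weight_scheme == "ds":
        fused = combine_all(bpas)
    else:
        sim = similarity_scores(bpas, normalization=config.sim_normalization)
        clar = clarity_scores(bpas, metric=config.clarity_metric)
        if config.weight_scheme == "proposed":
            weights = combined_weight(sim, clar, exponent_mode=config.exponent_mode)
        else:
            weights = baseline_weight(sim, clar, scheme=config.weight_scheme)
        discounted = discount_all(bpas, weights, divisor_mode=config.divisor_mode)
        fused = combine_all(discounted)
    return FusionResult(
        fused=fused.fused,
        conflict_k=fused.conflict_k,
        decision=_decide(fused.fused),
        weights=weights,
        bpas=bpas,
        sim=sim,
        clar=clar,
        config=config,
    )


def kappa_from_confusion(counts: np.ndarray) -> float:
    """Cohen's kappa K = (P0 - Pe) / (1 - Pe) from a square count matrix."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValidationError("empty confusion matrix")
    p0 = np.trace(counts) / total
    pe = float((counts.sum(axis=1) * counts.sum(axis=0)).sum()) / total**2
    if pe >= 1.0:
        return 1.0 if p0 >= 1.0 else 0.0
    return float((p0 - pe) / (1.0 - pe))


def kappa_band(kappa: float) -> str:
    """Verbal agreement band for a kappa value."""
    for upper, label in KAPPA_BANDS:
        if kappa <= upper:
            return label
    return KAPPA_BANDS[-1][1]


def evaluate(
    dataset: pd.DataFrame,
    prototypes: PrototypeTable,
    config: PipelineConfig | None = None,
    label_col: str = "label",
) -> EvaluationReport:
    """Classify every row and summarize: confusion matrix, per-class accuracy,
    sample-size-weighted accuracy, and Cohen's kappa with its verbal band."""
    config = config or PipelineConfig()
    if len(dataset) == 0:
        raise ValidationError("dataset is empty")
    if label_col not in dataset.columns:
        raise ValidationError(f"dataset has no label column {label_col!r}")
    labels = list(prototypes.frame.labels)
    truth = dataset[label_col].astype(str)
    unknown = set(truth) - set(labels)
    if unknown:
        raise ValidationError(f"dataset classes {sorted(unknown)} are not in the frame {labels!r}")
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    index = {c: i for i, c in enumerate(labels)}
    feats = dataset[list(prototypes.sensors)].to_numpy(dtype=float)
    for row, true_label in zip(feats, truth):
        result = classify(row, prototypes, config)
        counts[index[true_label], index[result.decision]] += 1
    confusion = pd.DataFrame(counts, index=labels, columns=labels)
    row_totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        per_class = np.where(row_totals > 0, np.diag(counts) / np.maximum(row_totals, 1), np.nan)
    per_class_accuracy = pd.Series(per_class, index=labels, name="accuracy")
    weighted = float(np.trace(counts) / counts.sum())
    kappa = kappa_from_confusion(counts)
    return EvaluationReport(
        confusion=confusion,
        per_class_accuracy=per_class_accuracy,
        weighted_accuracy=weighted,
        kappa=kappa,
        kappa_band=kappa_band(kappa),
        n=int(counts.sum()),
    )
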