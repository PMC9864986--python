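import logging

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

from dsfusion import (
    Frame,
    PipelineConfig,
    PrototypeTable,
    ValidationError,
    classify,
    evaluate,
    fit_prototypes,
    generate_bpa,
    kappa_band,
    kappa_from_confusion,
)
from dsfusion.errors import ConfigurationError
from dsfusion.synthetic_data import SyntheticConfig, activity_prototypes, generate_dataset

from .conftest import PRINTED_BPA_ROWS


class TestPipelineConfig:
    def test_defaults(self):
        config = PipelineConfig()
        assert config.weight_scheme == "proposed"
        assert config.divisor_mode == "frame_minus_one"

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"weight_scheme": "bogus"},
            {"clarity_metric": "bogus"},
            {"sim_normalization": "bogus"},
            {"exponent_mode": "bogus"},
            {"divisor_mode": "bogus"},
        ],
    )
    def test_vocabulary_checked(self, kwargs):
        with pytest.raises(ConfigurationError):
            PipelineConfig(**kwargs)


class TestFitPrototypes:
    def test_simple_mean(self):
        data = pd.DataFrame({"x": [1.0, 3.0, 10.0], "label": ["A", "A", "B"]})
        table = fit_prototypes(data)
        assert table.row("x") == pytest.approx([2.0, 10.0])
        assert table.frame.labels == ("A", "B")

    def test_zero_noise_round_trip(self, prototypes):
        data = generate_dataset(SyntheticConfig(noise_sd=0.0, n_per_class=4, seed=1))
        fitted = fit_prototypes(data, class_order=prototypes.frame.labels)
        assert fitted.values == pytest.approx(prototypes.values, abs=1e-12)
        assert fitted.sensors == prototypes.sensors

    def test_single_row_per_class(self):
        data = pd.DataFrame({"x": [5.0, 7.0], "y": [1.0, 2.0], "label": ["A", "B"]})
        table = fit_prototypes(data)
        assert table.values == pytest.approx(np.array([[5.0, 7.0], [1.0, 2.0]]))

    def test_missing_class_rejected(self):
        data = pd.DataFrame({"x": [1.0], "label": ["A"]})
        with pytest.raises(ValidationError):
            fit_prototypes(data, class_order=["A", "B"])

    def test_empty_dataset(self):
        with pytest.raises(ValidationError):
            fit_prototypes(pd.DataFrame({"x": [], "label": []}))

    def test_missing_label_column(self):
        with pytest.raises(ValidationError):
            fit_prototypes(pd.DataFrame({"x": [1.0]}))


class TestGenerateBpa:
    def test_bpm_row_matches_printed_rounding(self, prototypes, worked_reading):
        bpa = generate_bpa(worked_reading, prototypes, "bpm")
        got = bpa.singleton_array()
        assert tuple(np.round(got, 3)) == PRINTED_BPA_ROWS["bpm"]

    @pytest.mark.parametrize("sensor", ["acc", "gyro", "bpm"])
    def test_all_rows_within_tolerance(self, prototypes, worked_reading, sensor):
        bpa = generate_bpa(worked_reading, prototypes, sensor)
        assert bpa.singleton_array() == pytest.approx(PRINTED_BPA_ROWS[sensor], abs=1e-3)
        assert bpa.total() == pytest.approx(1.0, abs=1e-12)
        assert np.all(bpa.singleton_array() > 0)

    def test_exact_prototype_hit(self, prototypes):
        reading = {"acc": prototypes.row("acc")[2], "gyro": 0.39, "bpm": 101.0}
        bpa = generate_bpa(reading, prototypes, "acc")
        assert bpa.mass("walking") == pytest.approx(1.0, abs=1e-9)

    def test_equidistant_symmetry(self):
        table = PrototypeTable(Frame(("A", "B", "C")), ("s", "t"), np.array([[0.0, 2.0, 50.0], [0.0, 0.0, 0.0]]))
        bpa = generate_bpa({"s": 1.0, "t": 0.0}, table, "s")
        assert bpa.mass("A") == pytest.approx(bpa.mass("B"))
        assert bpa.mass("C") < bpa.mass("A")

    def test_monotone_toward_prototype(self, prototypes):
        masses = []
        for bpm in np.linspace(95.0, 103.4257, 15):
            bpa = generate_bpa({"acc": 9.7728, "gyro": 0.39, "bpm": bpm}, prototypes, "bpm")
            masses.append(bpa.mass("walking"))
        assert np.all(np.diff(masses) >= -1e-12)

    def test_unknown_sensor(self, prototypes, worked_reading):
        with pytest.raises(ValidationError):
            generate_bpa(worked_reading, prototypes, "magnetometer")


class TestClassify:
    def test_ds_scheme_reproduces_fusion_row(self, prototypes, worked_reading):
        result = classify(worked_reading, prototypes, PipelineConfig(weight_scheme="ds"))
        assert result.fused_array() == pytest.approx(
            [0.0496, 0.3901, 0.5602, 0.0001, 0.0000], abs=1e-3
        )
        assert result.decision == "walking"
        assert result.weights is None

    def test_proposed_scheme_decides_walking(self, prototypes, worked_reading):
        result = classify(worked_reading, prototypes, PipelineConfig(weight_scheme="proposed"))
        assert result.decision == "walking"
        assert result.fused.mass("walking") > result.fused.mass("standing")
        # intermediates retained for reporting
        assert result.sim is not None and result.clar is not None
        assert len(result.weights) == 3

    def test_agreeing_sensors_reinforce(self):
        table = PrototypeTable(Frame(("A", "B")), ("s1", "s2"), np.array([[0.0, 10.0], [0.0, 10.0]]))
        result = classify({"s1": 0.5, "s2": 0.5}, table, PipelineConfig(weight_scheme="ds"))
        assert result.decision == "A"
        for bpa in result.bpas:
            assert result.fused.mass("A") > bpa.mass("A")

    def test_sensor_order_irrelevant(self, prototypes, worked_reading):
        swapped = PrototypeTable(
            prototypes.frame,
            tuple(reversed(prototypes.sensors)),
            prototypes.values[::-1].copy(),
        )
        reading = dict(zip(prototypes.sensors, worked_reading))
        for scheme in ("ds", "proposed", "arithmetic_mean"):
            config = PipelineConfig(weight_scheme=scheme)
            a = classify(reading, prototypes, config)
            b = classify(reading, swapped, config)
            assert a.decision == b.decision
            assert a.fused_array() == pytest.approx(b.fused_array(), abs=1e-9)

    def test_tie_broken_by_frame_order(self, caplog):
        table = PrototypeTable(Frame(("A", "B")), ("s1", "s2"), np.array([[0.0, 2.0], [0.0, 2.0]]))
        with caplog.at_level(logging.WARNING, logger="dsfusion.activity_pipeline"):
            result = classify({"s1": 1.0, "s2": 1.0}, table, PipelineConfig(weight_scheme="ds"))
        assert result.decision == "A"
        assert any("tie" in rec.message for rec in caplog.records)

    def test_needs_two_sensors(self):
        table = PrototypeTable(Frame(("A", "B")), ("s1",), np.array([[0.0, 1.0]]))
        with pytest.raises(ValidationError):
            classify({"s1": 0.2}, table)


class TestKappa:
    def test_perfect_agreement(self):
        assert kappa_from_confusion(np.diag([5, 7, 3])) == pytest.approx(1.0)

    def test_chance_agreement(self):
        # predictions independent of truth with identical marginals
        counts = np.outer([10, 30], [10, 30]) / 40.0
        assert kappa_from_confusion(counts) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sklearn_oracle(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 30, size=(4, 4))
        counts[0, 0] += 1  # avoid the all-zero corner
        y_true, y_pred = [], []
        for i in range(4):
            for j in range(4):
                y_true += [i] * counts[i, j]
                y_pred += [j] * counts[i, j]
        assert kappa_from_confusion(counts) == pytest.approx(
            cohen_kappa_score(y_true, y_pred), abs=1e-12
        )

    @pytest.mark.parametrize(
        "value,band",
        [(0.1, "slight"), (0.3, "fair"), (0.5, "moderate"), (0.7, "substantial"), (0.95, "almost perfect"), (1.0, "almost perfect")],
    )
    def test_bands(self, value, band):
        assert kappa_band(value) == band


class TestEvaluate:
    @pytest.mark.parametrize("scheme", ["ds", "proposed", "conflict_only", "arithmetic_mean"])
    def test_zero_noise_is_perfect(self, prototypes, scheme):
        data = generate_dataset(SyntheticConfig(noise_sd=0.0, n_per_class=3, seed=2))
        report = evaluate(data, prototypes, PipelineConfig(weight_scheme=scheme))
        assert report.weighted_accuracy == 1.0
        assert report.kappa == pytest.approx(1.0)
        assert report.kappa_band == "almost perfect"
        assert np.all(report.per_class_accuracy.to_numpy() == 1.0)

    def test_confusion_row_sums(self, prototypes):
        data = generate_dataset(SyntheticConfig(noise_sd=(0.5, 0.5, 8.0), n_per_class=20, seed=3))
        report = evaluate(data, prototypes)
        row_sums = report.confusion.sum(axis=1)
        for cls in prototypes.frame.labels:
            assert row_sums[cls] == 20
        assert report.n == 100

    def test_empty_dataset(self, prototypes):
        with pytest.raises(ValidationError):
            evaluate(pd.DataFrame({"acc": [], "gyro": [], "bpm": [], "label": []}), prototypes)

    def test_unknown_class(self, prototypes):
        data = pd.DataFrame({"acc": [9.8], "gyro": [0.2], "bpm": [90.0], "label": ["swimming"]})
        with pytest.raises(ValidationError):
            evaluate(data, prototypes)

    def test_deterministic(self, prototypes):
        data = generate_dataset(SyntheticConfig(noise_sd=(0.3, 0.3, 5.0), n_per_class=10, seed=4))
        a = evaluate(data, prototypes)
        b = evaluate(data, prototypes)
        assert a.weighted_accuracy == b.weighted_accuracy
        assert a.kappa == b.kappa
        assert (a.confusion == b.confusion).all().all()


def test_fit_then_classify_recovers_labels(prototypes):
    """End to end on noisy synthetic data: prototypes fitted from one draw
    classify a second draw far better than chance."""
    train = generate_dataset(SyntheticConfig(noise_sd=(0.05, 0.05, 2.0), n_per_class=50, seed=5))
    test = generate_dataset(SyntheticConfig(noise_sd=(0.05, 0.05, 2.0), n_per_class=20, seed=6))
    fitted = fit_prototypes(train, class_order=prototypes.frame.labels)
    report = evaluate(test, fitted)
    assert report.weighted_accuracy > 0.8
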