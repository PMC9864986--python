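import numpy as np
import pytest

from dsfusion import Frame, make_mass
from dsfusion.synthetic_data import WORKED_EXAMPLE_READING, activity_prototypes

# Printed worked-example BPA rows (acc, gyro, bpm); the gyro row sums to
# 0.999 as printed, so construction normalizes.
PRINTED_BPA_ROWS = {
    "acc": (0.145, 0.724, 0.127, 0.003, 0.001),
    "gyro": (0.217, 0.249, 0.502, 0.018, 0.013),
    "bpm": (0.113, 0.155, 0.628, 0.078, 0.025),
}


@pytest.fixture
def frame_ab():
    return Frame(("A", "B"))


@pytest.fixture
def frame_abc():
    return Frame(("A", "B", "C"))


@pytest.fixture
def two_class_scenario(frame_ab):
    """Two fuzzy evidences agreeing on B plus one sharp dissenter on A."""
    m12 = make_mass(frame_ab, {"A": 0.3, "B": 0.7})
    m3 = make_mass(frame_ab, {"A": 0.9, "B": 0.1})
    return [m12, m12, m3]


@pytest.fixture(scope="session")
def prototypes():
    return activity_prototypes()


@pytest.fixture(scope="session")
def worked_reading():
    return WORKED_EXAMPLE_READING


@pytest.fixture
def printed_bpas(prototypes):
    frame = prototypes.frame
    return [
        make_mass(frame, {1 << i: v for i, v in enumerate(row)}, normalize=True)
        for row in PRINTED_BPA_ROWS.values()
    ]


def random_bayesian_mass(frame, rng):
    p = rng.dirichlet(np.ones(frame.n))
    return make_mass(frame, {1 << i: float(v) for i, v in enumerate(p)}, normalize=True)


def random_mass(frame, rng, n_focal=3):
    """Random BPA with possibly-compound focal sets."""
    subsets = rng.choice(np.arange(1, 1 << frame.n), size=min(n_focal, (1 << frame.n) - 1), replace=False)
    weights = rng.dirichlet(np.ones(len(subsets)))
    return make_mass(frame, {int(s): float(w) for s, w in zip(subsets, weights)}, normalize=True)
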