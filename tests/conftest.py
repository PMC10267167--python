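import numpy as np
import pytest

from foom import (
    ActivityProfileSpec,
    CardanTriplet,
    KinematicSignal,
    MisalignmentSpec,
    generate_ideal_signal,
    inject_misalignment,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20230614)


@pytest.fixture
def hinge_signal():
    """Pure flexion hinge, 0-60 deg over one cycle."""
    grid = np.linspace(0.0, 100.0, 101)
    flexion = 30.0 - 30.0 * np.cos(2.0 * np.pi * grid / 100.0)
    angles = np.column_stack([flexion, np.zeros(101), np.zeros(101)])
    return KinematicSignal(grid, angles, {"activity": "hinge"})


@pytest.fixture
def walking_signal():
    return generate_ideal_signal(ActivityProfileSpec(activity="walking"))


@pytest.fixture
def misaligned_hinge(hinge_signal):
    """Hinge corrupted by a known noiseless frame misalignment."""
    mis = MisalignmentSpec(femur=CardanTriplet(5.0, 10.0, -7.0),
                           tibia=CardanTriplet(-3.0, 4.0, 6.0))
    return hinge_signal, inject_misalignment(hinge_signal, mis), mis


def random_triplet(rng, beta_max=89.0, other_max=179.0):
    return CardanTriplet(
        float(rng.uniform(-other_max, other_max)),
        float(rng.uniform(-beta_max, beta_max)),
        float(rng.uniform(-other_max, other_max)),
    )
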