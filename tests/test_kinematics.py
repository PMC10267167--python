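"""Signal container, frame reorientation, and RMS/RMSE primitives."""

import numpy as np
import pytest

from foom import (
    CardanTriplet,
    FrameCorrection,
    KinematicSignal,
    component_rms,
    reorient_signal,
    resample_signal,
    signal_rmse,
)
from foom.rotations import (
    GimbalLockError,
    cardan_to_matrix,
    elementary_rotation,
    invert,
    matrix_to_cardan,
)

X = np.array([1.0, 0.0, 0.0])


def make_signal(angles, grid=None):
    angles = np.atleast_2d(np.asarray(angles, float))
    if grid is None:
        grid = np.linspace(0, 100, angles.shape[0])
    return KinematicSignal(grid, angles)


class TestKinematicSignal:
    def test_rejects_non_monotone_grid(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            KinematicSignal(np.array([0.0, 50.0, 50.0]), np.zeros((3, 3)))

    def test_rejects_short_signal(self):
        with pytest.raises(ValueError, match="at least 2"):
            KinematicSignal(np.array([0.0]), np.zeros((1, 3)))

    def test_rejects_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            KinematicSignal(np.array([0.0, 100.0]), np.zeros((3, 3)))


class TestReorientSignal:
    def test_identity_correction_is_noop(self, walking_signal):
        out = reorient_signal(walking_signal, FrameCorrection.identity())
        np.testing.assert_allclose(out.angles, walking_signal.angles,
                                   atol=1e-12)
        assert out.meta == walking_signal.meta

    def test_composition_law(self, rng, walking_signal):
        # reorient(reorient(S, C1), C2) == reorient(S, C12) where the
        # composed correction multiplies per segment: C_f1 C_f2, C_t1 C_t2
        for _ in range(10):
            p1, p2 = rng.uniform(-12, 12, 6), rng.uniform(-12, 12, 6)
            C1 = FrameCorrection.from_params(p1)
            C2 = FrameCorrection.from_params(p2)
            C12 = FrameCorrection(
                matrix_to_cardan(cardan_to_matrix(C1.femur)
                                 @ cardan_to_matrix(C2.femur)),
                matrix_to_cardan(cardan_to_matrix(C1.tibia)
                                 @ cardan_to_matrix(C2.tibia)))
            a = reorient_signal(reorient_signal(walking_signal, C1), C2)
            b = reorient_signal(walking_signal, C12)
            np.testing.assert_allclose(a.angles, b.angles, atol=1e-9)

    def test_crosstalk_mechanism_matches_matrix_oracle(self, hinge_signal):
        # a 10 deg frontal-frame error on a pure hinge must leak flexion
        # into the other two components, exactly as the per-timestep
        # matrix product predicts
        corr = FrameCorrection(CardanTriplet(0.0, 10.0, 0.0),
                               CardanTriplet.identity())
        out = reorient_signal(hinge_signal, corr)
        assert component_rms(out, 2) > 0.5
        assert component_rms(out, 3) > 0.5
        C_f = cardan_to_matrix(corr.femur)
        for i, row in enumerate(hinge_signal.angles):
            R_mod = invert(C_f) @ cardan_to_matrix(row)
            expected = matrix_to_cardan(R_mod)
            np.testing.assert_allclose(
                out.angles[i],
                [expected.alpha, expected.beta, expected.gamma], atol=1e-9)

    def test_hinge_conjugation_degeneracy(self, hinge_signal):
        # equal x-axis rotations of both frames leave a pure hinge intact
        q = CardanTriplet(17.0, 0.0, 0.0)
        out = reorient_signal(hinge_signal, FrameCorrection(q, q))
        np.testing.assert_allclose(out.angles[:, 0],
                                   hinge_signal.angles[:, 0], atol=1e-9)
        assert np.abs(out.angles[:, 1:]).max() < 1e-9

    def test_gimbal_lock_reports_timestep(self):
        # correction pushes the second timestep to exactly beta = 90 deg
        sig = make_signal([[0, 0, 0], [0, 85.0, 0], [10, 0, 0]])
        corr = FrameCorrection(CardanTriplet(0.0, -5.0, 0.0),
                               CardanTriplet.identity())
        with pytest.raises(GimbalLockError, match="timestep index 1"):
            reorient_signal(sig, corr)


class TestRmsPrimitives:
    def test_component_rms_hand_values(self):
        sig = make_signal([[3.0, 0.0, 2.0], [4.0, 0.0, 2.0]])
        assert component_rms(sig, 1) == pytest.approx(np.sqrt(12.5))
        assert component_rms(sig, 2) == 0.0
        assert component_rms(sig, 3) == pytest.approx(2.0)

    def test_component_rms_validates_index(self, walking_signal):
        with pytest.raises(ValueError, match="component index"):
            component_rms(walking_signal, 0)

    def test_component_rms_reorder_invariance(self, rng):
        vals = rng.normal(size=(20, 3))
        sig = make_signal(vals)
        perm = rng.permutation(20)
        sig2 = make_signal(vals[perm])
        for c in (1, 2, 3):
            assert component_rms(sig, c) == pytest.approx(
                component_rms(sig2, c), abs=1e-12)

    def test_signal_rmse_identical_and_offset(self, walking_signal):
        np.testing.assert_allclose(
            signal_rmse(walking_signal, walking_signal), np.zeros(3))
        shifted = walking_signal.with_angles(
            walking_signal.angles + np.array([1.0, 0.0, 0.0]))
        np.testing.assert_allclose(signal_rmse(walking_signal, shifted),
                                   [1.0, 0.0, 0.0], atol=1e-12)

    def test_signal_rmse_brute_force_oracle(self, rng):
        a = make_signal(rng.normal(size=(17, 3)))
        b = make_signal(rng.normal(size=(17, 3)))
        expected = [np.sqrt(sum((a.angles[t, i] - b.angles[t, i]) ** 2
                                for t in range(17)) / 17) for i in range(3)]
        np.testing.assert_allclose(signal_rmse(a, b), expected, atol=1e-12)
        np.testing.assert_allclose(signal_rmse(a, b), signal_rmse(b, a))

    def test_signal_rmse_refuses_mismatched_grids(self):
        a = make_signal(np.zeros((5, 3)))
        b = make_signal(np.zeros((6, 3)))
        with pytest.raises(ValueError, match="lengths differ"):
            signal_rmse(a, b)
        c = make_signal(np.zeros((5, 3)), grid=np.linspace(0, 90, 5))
        with pytest.raises(ValueError, match="grids differ"):
            signal_rmse(a, c)


class TestResample:
    def test_linear_resample_preserves_straight_lines(self):
        grid = np.array([0.0, 50.0, 100.0])
        sig = KinematicSignal(grid, np.column_stack([grid / 10,
                                                     np.zeros(3),
                                                     np.zeros(3)]))
        out = resample_signal(sig, 11)
        np.testing.assert_allclose(out.angles[:, 0], out.cycle_grid / 10,
                                   atol=1e-12)
        assert len(out) == 11
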