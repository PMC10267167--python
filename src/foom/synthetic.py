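"""Synthetic flexion-dominant joint kinematics with known frame misalignment.

Real bench datasets of this kind (robotic joint-simulator cycles measured
by IMUs) are not openly distributable, so this module generates the study
conditions instead: activity cycles with a dominant flexion/extension
component and small frontal/transverse rotations, plus a way to corrupt
them with *known* fixed frame misalignments. Because the injected
misalignment is the exact algebraic inverse of the correction operation,
every optimisation claim can be tested against ground truth.

The default waveforms are stylised versions of three activities of daily
living:

* ``walking`` — two-peak knee flexion curve spanning roughly 0-60 deg
  (small stance peak, large swing peak);
* ``stair_descent`` — single broad peak to ~90 deg;
* ``sit_stand_sit`` — flexed at both ends (~90 deg), extended mid-cycle.

Frontal (ab/adduction) and transverse (int/ext rotation) components are
low-amplitude sinusoids. The coefficients are illustrative of shape and
range only; all are overridable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .kinematics import FrameCorrection, KinematicSignal
from .rotations import (CardanTriplet, batch_matrix_to_cardan,
                        cardan_to_matrix, invert)

__all__ = [
    "ActivityProfileSpec",
    "MisalignmentSpec",
    "SyntheticTrial",
    "generate_ideal_signal",
    "inject_misalignment",
    "make_trial_set",
    "ACTIVITIES",
]

# Fourier description of flexion: offset + sum of (amplitude_deg, harmonic,
# phase_rad) cosine terms evaluated on the cycle fraction p in [0, 1].
_WALKING_FLEXION = {
    "offset": 26.0,
    "harmonics": [(22.0, 1, math.pi), (9.0, 2, math.pi / 2)],
}
_STAIR_FLEXION = {
    "offset": 48.0,
    "harmonics": [(42.0, 1, math.pi)],
}
_SIT_STAND_FLEXION = {
    "offset": 50.0,
    "harmonics": [(40.0, 1, 0.0)],
}

ACTIVITIES = ("walking", "stair_descent", "sit_stand_sit")

_FLEXION_DEFAULTS = {
    "walking": _WALKING_FLEXION,
    "stair_descent": _STAIR_FLEXION,
    "sit_stand_sit": _SIT_STAND_FLEXION,
}


@dataclass(frozen=True)
class ActivityProfileSpec:
    """Parameters of one synthetic activity cycle.

    ``flexion_offset_deg`` and ``flexion_harmonics`` define the dominant
    component as a cosine series a_k * cos(2*pi*k*p + phase) over cycle
    fraction p; ``None`` selects the built-in defaults for ``activity``.
    Frontal and transverse components are single sinusoids of the given
    amplitudes (degrees). ``cyclic`` specs evaluate on a grid whose first
    and last samples coincide in phase, so the waveform closes exactly.
    """

    activity: str = "walking"
    n_samples: int = 101
    flexion_offset_deg: float | None = None
    flexion_harmonics: Sequence[tuple[float, int, float]] | None = None
    frontal_amplitude_deg: float = 3.0
    transverse_amplitude_deg: float = 5.0
    cyclic: bool = True

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITIES and self.activity != "custom":
            raise ValueError(f"unknown activity {self.activity!r}; "
                             f"expected one of {ACTIVITIES} or 'custom'")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.frontal_amplitude_deg < 0 or self.transverse_amplitude_deg < 0:
            raise ValueError("amplitudes must be nonnegative")
        if self.activity == "custom" and self.flexion_harmonics is None:
            raise ValueError("custom activity requires explicit flexion terms")

    def flexion_terms(self) -> tuple[float, list[tuple[float, int, float]]]:
        if self.flexion_harmonics is not None:
            offset = self.flexion_offset_deg or 0.0
            return float(offset), [tuple(t) for t in self.flexion_harmonics]
        d = _FLEXION_DEFAULTS[self.activity]
        offset = d["offset"] if self.flexion_offset_deg is None \
            else self.flexion_offset_deg
        return float(offset), list(d["harmonics"])


@dataclass(frozen=True)
class MisalignmentSpec:
    """Ground-truth frame misalignment plus optional angle noise."""

    femur: CardanTriplet = field(default_factory=CardanTriplet.identity)
    tibia: CardanTriplet = field(default_factory=CardanTriplet.identity)
    noise_sd_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_deg < 0:
            raise ValueError("noise_sd_deg must be nonnegative")

    def as_correction(self) -> FrameCorrection:
        """The frame correction that exactly undoes this misalignment."""
        return FrameCorrection(self.femur, self.tibia)


@dataclass(frozen=True)
class SyntheticTrial:
    """One subject-activity trial: ideal signal, misaligned raw signal,
    and the ground-truth correction that maps raw back to ideal."""

    ideal: KinematicSignal
    raw: KinematicSignal
    truth: FrameCorrection


def _evaluate_flexion(spec: ActivityProfileSpec, p: np.ndarray) -> np.ndarray:
    offset, harmonics = spec.flexion_terms()
    out = np.full_like(p, offset)
    for amp, k, phase in harmonics:
        out = out + amp * np.cos(2.0 * math.pi * k * p + phase)
    return out


def generate_ideal_signal(spec: ActivityProfileSpec) -> KinematicSignal:
    """Deterministic cross-talk-consistent activity cycle on a 0-100% grid."""
    grid = np.linspace(0.0, 100.0, spec.n_samples)
    p = grid / 100.0
    flexion = _evaluate_flexion(spec, p)
    two_pi_p = 2.0 * math.pi * p
    frontal = spec.frontal_amplitude_deg * np.sin(two_pi_p)
    transverse = spec.transverse_amplitude_deg * np.sin(two_pi_p + math.pi / 3) \
        - spec.transverse_amplitude_deg * math.sin(math.pi / 3)
    if spec.cyclic:
        # the harmonics close by construction; enforce bit-exact closure
        flexion[-1] = flexion[0]
        frontal[-1] = frontal[0]
        transverse[-1] = transverse[0]
    angles = np.column_stack([flexion, frontal, transverse])
    return KinematicSignal(grid, angles, {"activity": spec.activity,
                                          "source": "synthetic-ideal"})


def inject_misalignment(ideal: KinematicSignal,
                        mis: MisalignmentSpec) -> KinematicSignal:
    """Corrupt a signal with a fixed frame misalignment (plus noise).

    Constructs raw frames differing from the ideal ones by the fixed
    rotations M_f (femur) and M_t (tibia):

        R_raw(t) = M_f @ R_ideal(t) @ M_t^-1

    so that reorienting the result by the same pair as a
    :class:`FrameCorrection` recovers the ideal signal exactly. Gaussian
    per-sample angle noise of sd ``noise_sd_deg`` is then added in angle
    space, seeded by ``mis.seed``.
    """
    M_f = cardan_to_matrix(mis.femur)
    M_t_inv = invert(cardan_to_matrix(mis.tibia))
    out = batch_matrix_to_cardan(M_f @ ideal.matrices() @ M_t_inv)
    if mis.noise_sd_deg > 0:
        rng = np.random.default_rng(mis.seed)
        out = out + rng.normal(0.0, mis.noise_sd_deg, size=out.shape)
    meta = dict(ideal.meta)
    meta["source"] = "synthetic-raw"
    meta["noise_sd_deg"] = mis.noise_sd_deg
    return KinematicSignal(ideal.cycle_grid.copy(), out, meta)


def make_trial_set(profile: ActivityProfileSpec,
                   n_subjects: int,
                   misalignment_range_deg: float,
                   seed: int,
                   noise_sd_deg: float = 0.0) -> list[SyntheticTrial]:
    """Reproducible set of misaligned trials with known ground truth.

    Each subject receives an independent misalignment with all six angles
    drawn uniformly in +-``misalignment_range_deg``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if misalignment_range_deg < 0:
        raise ValueError("misalignment_range_deg must be nonnegative")
    rng = np.random.default_rng(seed)
    ideal = generate_ideal_signal(profile)
    trials: list[SyntheticTrial] = []
    for subj in range(n_subjects):
        angles = rng.uniform(-misalignment_range_deg, misalignment_range_deg,
                             size=6)
        noise_seed = int(rng.integers(0, 2 ** 31 - 1))
        mis = MisalignmentSpec(
            femur=CardanTriplet.from_array(angles[:3]),
            tibia=CardanTriplet.from_array(angles[3:]),
            noise_sd_deg=noise_sd_deg,
            seed=noise_seed,
        )
        ideal_s = KinematicSignal(ideal.cycle_grid.copy(), ideal.angles.copy(),
                                  {**ideal.meta, "subject": subj})
        raw = inject_misalignment(ideal_s, mis)
        trials.append(SyntheticTrial(ideal=ideal_s, raw=raw,
                                     truth=mis.as_correction()))
    return trials
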