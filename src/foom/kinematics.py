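"""Kinematic time series and the frame-reorientation operation.

A :class:`KinematicSignal` holds one activity cycle (e.g. one gait cycle,
0-100%) of joint rotations as per-timestep Cardan triplets in degrees. A
:class:`FrameCorrection` is a pair of *fixed* rotations, one applied to the
proximal (femoral) frame and one to the distal (tibial) frame; because both
raw and corrected frames are rigidly attached to the same segments, the
correction carries no time index.

Reorientation applies the corrections at every timestep,

    R_mod(t) = C_femur^-1  @  R_raw(t)  @  C_tibia,

and re-decomposes each corrected matrix back to Cardan angles. This is the
mechanism by which a fixed frame misalignment turns pure flexion into
spurious ab/adduction and int/external rotation (cross-talk) — and by which
the right correction removes it again.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

from .rotations import (
    CardanTriplet,
    GimbalLockError,
    DEFAULT_GIMBAL_TOL_DEG,
    batch_cardan_to_matrix,
    batch_matrix_to_cardan,
    cardan_to_matrix,
    matrix_to_cardan,
    invert,
)

__all__ = [
    "KinematicSignal",
    "FrameCorrection",
    "reorient_signal",
    "component_rms",
    "signal_rmse",
    "resample_signal",
]

_GRID_TOL = 1e-9

#: Human-readable names of the three rotation components, index 1-3.
COMPONENT_NAMES = {1: "flexion/extension",
                   2: "ab/adduction",
                   3: "int/external rotation"}


@dataclass(frozen=True)
class KinematicSignal:
    """One cycle of rotational joint kinematics.

    Parameters
    ----------
    cycle_grid : array of float
        Strictly increasing percent-of-cycle values, typically 0-100.
    angles : (N, 3) array of float
        Cardan triplets (alpha, beta, gamma) in degrees, one row per
        timestep, intrinsic-XYZ convention.
    meta : mapping
        Free-form labels (subject, activity, source system, ...).
    """

    cycle_grid: np.ndarray
    angles: np.ndarray
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        grid = np.asarray(self.cycle_grid, dtype=float)
        ang = np.asarray(self.angles, dtype=float)
        if grid.ndim != 1 or grid.size < 2:
            raise ValueError("cycle_grid must be 1-D with at least 2 samples")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("cycle_grid must be strictly increasing")
        if ang.shape != (grid.size, 3):
            raise ValueError(
                f"angles must have shape ({grid.size}, 3), got {ang.shape}")
        if not np.all(np.isfinite(ang)):
            raise ValueError("angles must be finite")
        object.__setattr__(self, "cycle_grid", grid)
        object.__setattr__(self, "angles", ang)
        object.__setattr__(self, "meta", dict(self.meta))

    def __len__(self) -> int:
        return self.cycle_grid.size

    def __iter__(self) -> Iterator[CardanTriplet]:
        for row in self.angles:
            yield CardanTriplet.from_array(row)

    @classmethod
    def from_triplets(cls, cycle_grid, triplets: Sequence[CardanTriplet],
                      meta: Mapping[str, object] | None = None) -> "KinematicSignal":
        ang = np.array([t.as_array() for t in triplets], dtype=float)
        return cls(np.asarray(cycle_grid, dtype=float), ang, meta or {})

    def matrices(self) -> np.ndarray:
        """Per-timestep rotation matrices, shape (N, 3, 3)."""
        return batch_cardan_to_matrix(self.angles)

    def component(self, index: int) -> np.ndarray:
        """One angle component over the cycle; index is 1, 2 or 3."""
        if index not in (1, 2, 3):
            raise ValueError(f"component index must be 1, 2 or 3, got {index}")
        return self.angles[:, index - 1]

    def with_angles(self, angles: np.ndarray) -> "KinematicSignal":
        return KinematicSignal(self.cycle_grid.copy(), angles, dict(self.meta))

    def same_grid(self, other: "KinematicSignal", tol: float = _GRID_TOL) -> bool:
        return (len(self) == len(other)
                and bool(np.allclose(self.cycle_grid, other.cycle_grid,
                                     atol=tol, rtol=0.0)))


@dataclass(frozen=True)
class FrameCorrection:
    """Fixed corrective rotations of the femoral and tibial frames.

    Each triplet parameterises the rotation from the raw to the corrected
    segment frame as intrinsic-XYZ Cardan angles in degrees; the pair is
    constant over the activity cycle.
    """

    femur: CardanTriplet
    tibia: CardanTriplet

    def __post_init__(self) -> None:
        # round-trip check guards |beta| < 90 for both triplets
        for name, trip in (("femur", self.femur), ("tibia", self.tibia)):
            try:
                matrix_to_cardan(cardan_to_matrix(trip))
            except GimbalLockError as exc:
                raise ValueError(
                    f"{name} correction is gimbal-degenerate: {exc}") from exc

    @classmethod
    def identity(cls) -> "FrameCorrection":
        return cls(CardanTriplet.identity(), CardanTriplet.identity())

    @classmethod
    def from_params(cls, params) -> "FrameCorrection":
        """Build from a flat 6-vector (femur alpha,beta,gamma, tibia ditto)."""
        p = np.asarray(params, dtype=float)
        if p.shape != (6,):
            raise ValueError(f"expected 6 parameters, got shape {p.shape}")
        return cls(CardanTriplet.from_array(p[:3]),
                   CardanTriplet.from_array(p[3:]))

    def as_params(self) -> np.ndarray:
        return np.concatenate([self.femur.as_array(), self.tibia.as_array()])

    def matrices(self) -> tuple[np.ndarray, np.ndarray]:
        return cardan_to_matrix(self.femur), cardan_to_matrix(self.tibia)


def reorient_signal(raw: KinematicSignal, corr: FrameCorrection,
                    gimbal_tol_deg: float = DEFAULT_GIMBAL_TOL_DEG) -> KinematicSignal:
    """Apply fixed frame corrections to every timestep of a signal.

    Computes ``C_femur^-1 @ R_raw(t) @ C_tibia`` per timestep and
    re-decomposes to Cardan angles. The cycle grid and metadata are
    preserved.

    Raises
    ------
    GimbalLockError
        If any corrected matrix lands within the gimbal tolerance of the
        |beta| = 90 deg singularity; the error names the timestep.
    """
    C_f, C_t = corr.matrices()
    R_mod = invert(C_f) @ raw.matrices() @ C_t
    out = batch_matrix_to_cardan(R_mod, gimbal_tol_deg)
    return raw.with_angles(out)


def component_rms(signal: KinematicSignal, component: int) -> float:
    """Root-mean-square of one angle component over the cycle, degrees.

    The mean is over the number of samples N (uniform weight per sample).
    """
    vals = signal.component(component)
    return float(np.sqrt(np.mean(vals ** 2)))


def signal_rmse(a: KinematicSignal, b: KinematicSignal) -> np.ndarray:
    """Per-component RMSE between two signals on the same grid, degrees.

    Returns a length-3 array (flexion, ab/adduction, int/ext rotation).
    Signals must share length and cycle grid exactly; no implicit
    resampling is performed (use :func:`resample_signal` explicitly).
    """
    if len(a) != len(b):
        raise ValueError(f"signal lengths differ: {len(a)} vs {len(b)}")
    if not a.same_grid(b):
        raise ValueError("cycle grids differ; resample explicitly before "
                         "computing RMSE")
    diff = a.angles - b.angles
    return np.sqrt(np.mean(diff ** 2, axis=0))


def resample_signal(signal: KinematicSignal, n_samples: int) -> KinematicSignal:
    """Linear resampling onto a uniform grid spanning the original range.

    Opt-in utility: the RMS/RMSE primitives above deliberately refuse
    mismatched grids, so any resampling must happen here, visibly.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    new_grid = np.linspace(signal.cycle_grid[0], signal.cycle_grid[-1], n_samples)
    new_angles = np.column_stack([
        np.interp(new_grid, signal.cycle_grid, signal.angles[:, j])
        for j in range(3)
    ])
    meta = dict(signal.meta)
    meta["resampled_from_n"] = len(signal)
    return KinematicSignal(new_grid, new_angles, meta)
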