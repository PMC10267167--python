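"""Convention-pinned rotation algebra for joint kinematics.

All public angles are in degrees. Rotations are *active* and act on column
vectors by left multiplication. The joint angle convention is the intrinsic
X-Y-Z Cardan (Tait-Bryan) sequence used to express knee kinematics in the
Grood-Suntay sense: rotate first about the (flexion) x-axis by ``alpha``,
then about the new y-axis by ``beta`` (ab/adduction), then about the newest
z-axis by ``gamma`` (int/external rotation).  As a matrix product this is

    R = R(x, alpha) @ R(y, beta) @ R(z, gamma)

which is numerically identical to the extrinsic Z-Y-X sequence with the
same three angles.  The decomposition takes the unique branch with
``beta`` in the open interval (-90, 90) degrees; configurations with
``|beta|`` within ``gimbal_tol_deg`` of 90 degrees are treated as gimbal
locked and raise :class:`GimbalLockError` rather than returning a silently
non-unique answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CardanTriplet",
    "GimbalLockError",
    "DEFAULT_GIMBAL_TOL_DEG",
    "elementary_rotation",
    "cardan_to_matrix",
    "matrix_to_cardan",
    "compose",
    "invert",
    "is_rotation_matrix",
    "batch_cardan_to_matrix",
    "batch_matrix_to_cardan",
]

#: Default margin (degrees) from the |beta| = 90 deg singularity below which
#: the Cardan decomposition is considered gimbal locked.
DEFAULT_GIMBAL_TOL_DEG = 1e-6

_ORTHO_TOL = 1e-9


class GimbalLockError(ValueError):
    """Raised when a Cardan decomposition is requested at |beta| ~ 90 deg.

    Flexion-dominant joint signals never legitimately approach the
    singularity, so hitting it indicates corrupt input or a wildly wrong
    frame correction; failing loudly is deliberate.
    """

    def __init__(self, message: str, timestep: int | None = None):
        if timestep is not None:
            message = f"{message} (timestep index {timestep})"
        super().__init__(message)
        self.timestep = timestep


@dataclass(frozen=True)
class CardanTriplet:
    """One intrinsic-XYZ Cardan angle set, in degrees.

    Attributes
    ----------
    alpha : float
        Rotation about x (clinically: flexion/extension).
    beta : float
        Rotation about the intermediate y (ab/adduction). Must stay clear
        of +-90 deg for the decomposition to be unique.
    gamma : float
        Rotation about the final z (int/external rotation).
    """

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"CardanTriplet.{name} must be finite, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma], dtype=float)

    @classmethod
    def from_array(cls, a) -> "CardanTriplet":
        a = np.asarray(a, dtype=float)
        if a.shape != (3,):
            raise ValueError(f"expected 3 angles, got shape {a.shape}")
        return cls(float(a[0]), float(a[1]), float(a[2]))

    @classmethod
    def identity(cls) -> "CardanTriplet":
        return cls(0.0, 0.0, 0.0)


def _deg2rad(deg: float) -> float:
    return math.radians(deg)


def is_rotation_matrix(R: np.ndarray, tol: float = _ORTHO_TOL) -> bool:
    """True when R is proper orthonormal (R^T R = I, det = +1) within tol."""
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        return False
    if not np.all(np.isfinite(R)):
        return False
    if not np.allclose(R.T @ R, np.eye(3), atol=tol, rtol=0.0):
        return False
    return abs(float(np.linalg.det(R)) - 1.0) <= tol


def _check_rotation(R: np.ndarray, what: str = "matrix") -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError(f"{what} must be 3x3, got shape {R.shape}")
    if not is_rotation_matrix(R):
        raise ValueError(f"{what} is not a proper rotation matrix "
                         f"(orthonormality/determinant check failed)")
    return R


def elementary_rotation(axis, theta_deg: float) -> np.ndarray:
    """Active rotation by ``theta_deg`` degrees about a unit 3-vector.

    Right-hand rule: positive angles rotate counter-clockwise when the
    axis points at the viewer.
    """
    axis = np.asarray(axis, dtype=float)
    if axis.shape != (3,):
        raise ValueError(f"axis must be a 3-vector, got shape {axis.shape}")
    norm = float(np.linalg.norm(axis))
    if abs(norm - 1.0) > 1e-9:
        raise ValueError(f"axis must have unit norm (got |axis| = {norm!r})")
    t = _deg2rad(theta_deg)
    c, s = math.cos(t), math.sin(t)
    x, y, z = axis
    C = 1.0 - c
    # Rodrigues form
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


_X = np.array([1.0, 0.0, 0.0])
_Y = np.array([0.0, 1.0, 0.0])
_Z = np.array([0.0, 0.0, 1.0])


def cardan_to_matrix(angles: CardanTriplet | tuple | list | np.ndarray) -> np.ndarray:
    """Rotation matrix of an intrinsic-XYZ Cardan triplet (degrees).

    Computes ``R(x, alpha) @ R(y, beta) @ R(z, gamma)`` in closed form.
    """
    if isinstance(angles, CardanTriplet):
        a, b, g = angles.alpha, angles.beta, angles.gamma
    else:
        a, b, g = (float(v) for v in np.asarray(angles, dtype=float))
    ca, sa = math.cos(_deg2rad(a)), math.sin(_deg2rad(a))
    cb, sb = math.cos(_deg2rad(b)), math.sin(_deg2rad(b))
    cg, sg = math.cos(_deg2rad(g)), math.sin(_deg2rad(g))
    # closed form of Rx(a) @ Ry(b) @ Rz(g)
    return np.array([
        [cb * cg, -cb * sg, sb],
        [ca * sg + sa * sb * cg, ca * cg - sa * sb * sg, -sa * cb],
        [sa * sg - ca * sb * cg, sa * cg + ca * sb * sg, ca * cb],
    ])


def matrix_to_cardan(
    R: np.ndarray,
    gimbal_tol_deg: float = DEFAULT_GIMBAL_TOL_DEG,
    *,
    timestep: int | None = None,
    validate: bool = True,
) -> CardanTriplet:
    """Unique intrinsic-XYZ decomposition with beta in (-90, 90) degrees.

    For this sequence ``R[0, 2] = sin(beta)``; beta is taken on the
    principal arcsine branch and alpha, gamma follow from atan2 of the
    remaining entries.

    Raises
    ------
    GimbalLockError
        If ``|beta|`` is within ``gimbal_tol_deg`` degrees of 90, where
        alpha and gamma are no longer separable.
    """
    if validate:
        R = _check_rotation(R)
    else:
        R = np.asarray(R, dtype=float)
    sb = float(np.clip(R[0, 2], -1.0, 1.0))
    # |beta| >= 90 - tol  <=>  |sin beta| >= sin(90 - tol) = cos(tol)
    if abs(sb) >= math.cos(_deg2rad(gimbal_tol_deg)):
        raise GimbalLockError(
            f"gimbal lock: |sin(beta)| = {abs(sb):.12f}, beta within "
            f"{gimbal_tol_deg} deg of +-90 deg; Cardan decomposition is "
            f"not unique", timestep=timestep)
    beta = math.degrees(math.asin(sb))
    alpha = math.degrees(math.atan2(-R[1, 2], R[2, 2]))
    gamma = math.degrees(math.atan2(-R[0, 1], R[0, 0]))
    return CardanTriplet(alpha, beta, gamma)


def batch_cardan_to_matrix(angles_deg: np.ndarray) -> np.ndarray:
    """Rotation matrices for an (N, 3) stack of Cardan triplets (degrees)."""
    ang = np.radians(np.asarray(angles_deg, dtype=float))
    ca, sa = np.cos(ang[:, 0]), np.sin(ang[:, 0])
    cb, sb = np.cos(ang[:, 1]), np.sin(ang[:, 1])
    cg, sg = np.cos(ang[:, 2]), np.sin(ang[:, 2])
    R = np.empty((ang.shape[0], 3, 3))
    R[:, 0, 0] = cb * cg
    R[:, 0, 1] = -cb * sg
    R[:, 0, 2] = sb
    R[:, 1, 0] = ca * sg + sa * sb * cg
    R[:, 1, 1] = ca * cg - sa * sb * sg
    R[:, 1, 2] = -sa * cb
    R[:, 2, 0] = sa * sg - ca * sb * cg
    R[:, 2, 1] = sa * cg + ca * sb * sg
    R[:, 2, 2] = ca * cb
    return R


def batch_matrix_to_cardan(R: np.ndarray,
                           gimbal_tol_deg: float = DEFAULT_GIMBAL_TOL_DEG
                           ) -> np.ndarray:
    """Cardan triplets (degrees) for an (N, 3, 3) stack of rotations.

    Raises :class:`GimbalLockError` naming the first offending timestep
    when any matrix sits within the gimbal tolerance of |beta| = 90 deg.
    Orthonormality is the caller's responsibility (inputs are assumed to
    be products of valid rotations).
    """
    R = np.asarray(R, dtype=float)
    sb = np.clip(R[:, 0, 2], -1.0, 1.0)
    bad = np.abs(sb) >= math.cos(_deg2rad(gimbal_tol_deg))
    if np.any(bad):
        i = int(np.argmax(bad))
        raise GimbalLockError(
            f"gimbal lock: |sin(beta)| = {abs(sb[i]):.12f} within "
            f"{gimbal_tol_deg} deg of +-90 deg", timestep=i)
    out = np.empty((R.shape[0], 3))
    out[:, 0] = np.degrees(np.arctan2(-R[:, 1, 2], R[:, 2, 2]))
    out[:, 1] = np.degrees(np.arcsin(sb))
    out[:, 2] = np.degrees(np.arctan2(-R[:, 0, 1], R[:, 0, 0]))
    return out


def compose(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Matrix product A @ B (apply B first when acting on column vectors)."""
    return np.asarray(A, dtype=float) @ np.asarray(B, dtype=float)


def invert(A: np.ndarray) -> np.ndarray:
    """Inverse of a rotation matrix, i.e. its transpose."""
    return np.asarray(A, dtype=float).T.copy()
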