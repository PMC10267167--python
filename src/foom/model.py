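"""The Frame Orientation Optimisation Method (FOOM).

Given a raw kinematic signal, FOOM solves for a pair of fixed corrective
rotations of the proximal (femoral) and distal (tibial) segment frames —
six Cardan angles in total — that minimise one of two costs:

* **align** mode (a reference signal is available): the sum over the three
  rotation components of the RMSE between the corrected signal and the
  reference,

      sum_{i=1..3} sqrt( (1/N) sum_t (r_mod,i(t) - r_ref,i(t))^2 );

* **standalone** mode (self-contained, no reference): the sum of the RMS
  of the two non-dominant components of the corrected signal,

      sum_{i=2,3} sqrt( (1/N) sum_t r_mod,i(t)^2 ),

  which maximises the dominant (flexion) component and hence removes
  cross-talk without needing ground truth.

The minimisation runs a Levenberg-Marquardt least-squares pass on the
stacked per-sample residuals (whose squared sum is a monotone surrogate of
the printed cost), followed by a derivative-free polish of the exact
sum-of-RMS cost. Both objectives share their minimisers in the noiseless
compensable case (both reach zero); the polish removes any residual
discrepancy otherwise.

The interface follows the model/results idiom: build a
:class:`FrameOrientationModel` from data, call :meth:`fit`, and read the
estimates off the returned :class:`FrameOrientationResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares, minimize

from .kinematics import (
    FrameCorrection,
    KinematicSignal,
    component_rms,
    reorient_signal,
    signal_rmse,
)
from .rotations import (
    CardanTriplet,
    batch_matrix_to_cardan,
    cardan_to_matrix,
    compose,
    elementary_rotation,
    matrix_to_cardan,
)

__all__ = [
    "OptimisationSettings",
    "FrameOrientationModel",
    "FrameOrientationResults",
    "cost_align",
    "cost_standalone",
    "optimise_align",
    "optimise_standalone",
    "correction_discrepancy_deg",
]

_X_AXIS = np.array([1.0, 0.0, 0.0])


@dataclass(frozen=True)
class OptimisationSettings:
    """Tunable knobs of a FOOM fit.

    mode : 'align' or 'standalone'.
    max_iterations : cap on optimiser iterations/evaluations.
    tolerance : convergence threshold on cost change; also the flat-
        direction detection threshold in standalone mode.
    flexion_penalty_weight : weight of an optional penalty on deviation of
        the corrected flexion component from the raw one; keeps the
        corrected signal close to the measured flexion when its absolute
        values are clinically meaningful. Default 0 (off).
    max_correction_deg : optional bound on every correction angle.
    restarts : number of optimiser starts; the first is always the
        identity correction, further starts are drawn uniformly at random
        (seeded) within +-max_correction_deg (or +-30 deg if unbounded).
    seed : seed for the multistart draw (only used when restarts > 1).
    """

    mode: str = "standalone"
    max_iterations: int = 500
    tolerance: float = 1e-10
    flexion_penalty_weight: float = 0.0
    max_correction_deg: float | None = None
    restarts: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("align", "standalone"):
            raise ValueError(f"mode must be 'align' or 'standalone', "
                             f"got {self.mode!r}")
        if self.flexion_penalty_weight < 0:
            raise ValueError("flexion_penalty_weight must be >= 0")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_correction_deg is not None and self.max_correction_deg <= 0:
            raise ValueError("max_correction_deg must be positive")


# ---------------------------------------------------------------------------
# cost functions

def cost_align(raw: KinematicSignal, reference: KinematicSignal,
               corr: FrameCorrection,
               flexion_penalty_weight: float = 0.0) -> float:
    """Sum of per-component RMSEs between corrected signal and reference."""
    modified = reorient_signal(raw, corr)
    cost = float(np.sum(signal_rmse(modified, reference)))
    if flexion_penalty_weight > 0:
        cost += flexion_penalty_weight * float(signal_rmse(modified, raw)[0])
    return cost


def cost_standalone(raw: KinematicSignal, corr: FrameCorrection,
                    flexion_penalty_weight: float = 0.0) -> float:
    """RMS of the two non-dominant components of the corrected signal."""
    modified = reorient_signal(raw, corr)
    cost = component_rms(modified, 2) + component_rms(modified, 3)
    if flexion_penalty_weight > 0:
        cost += flexion_penalty_weight * float(signal_rmse(modified, raw)[0])
    return cost


# ---------------------------------------------------------------------------
# results object

@dataclass(frozen=True)
class FrameOrientationResults:
    """Estimates and diagnostics from one FOOM fit."""

    correction: FrameCorrection
    modified: KinematicSignal
    cost_initial: float
    cost_final: float
    converged: bool
    n_iterations: int
    degenerate_warning: bool
    degenerate_message: str
    mode: str
    settings: OptimisationSettings

    @property
    def params(self) -> np.ndarray:
        """Flat 6-vector of correction angles (femur xyz, tibia xyz), deg."""
        return self.correction.as_params()

    def summary(self) -> str:
        p = self.params
        lines = [
            "Frame Orientation Optimisation Method results",
            "=" * 45,
            f"mode:                 {self.mode}",
            f"samples:              {len(self.modified)}",
            f"cost at identity:     {self.cost_initial:.6f} deg",
            f"cost at optimum:      {self.cost_final:.6f} deg",
            f"converged:            {self.converged}",
            f"function evaluations: {self.n_iterations}",
            "",
            "correction angles (intrinsic XYZ, degrees)",
            f"  femur: alpha={p[0]:+9.4f}  beta={p[1]:+9.4f}  gamma={p[2]:+9.4f}",
            f"  tibia: alpha={p[3]:+9.4f}  beta={p[4]:+9.4f}  gamma={p[5]:+9.4f}",
        ]
        if self.degenerate_warning:
            lines += ["", f"WARNING: {self.degenerate_message}"]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "correction": {
                "femur_deg": list(self.correction.femur.as_array()),
                "tibia_deg": list(self.correction.tibia.as_array()),
            },
            "cost_initial_deg": self.cost_initial,
            "cost_final_deg": self.cost_final,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "degenerate_warning": self.degenerate_warning,
            "degenerate_message": self.degenerate_message,
        }


# ---------------------------------------------------------------------------
# model

class FrameOrientationModel:
    """FOOM as a fitted model: raw signal in, frame corrections out.

    Parameters
    ----------
    raw : KinematicSignal
        The signal whose segment frames are to be corrected.
    reference : KinematicSignal, optional
        When given, the fit runs in *align* mode and drives the corrected
        signal toward this reference; otherwise *standalone* mode
        minimises the non-dominant components of the corrected signal
        itself.
    """

    def __init__(self, raw: KinematicSignal,
                 reference: KinematicSignal | None = None):
        self.raw = raw
        self.reference = reference
        if reference is not None and not raw.same_grid(reference):
            raise ValueError("raw and reference signals must share an "
                             "identical cycle grid")
        self.mode = "align" if reference is not None else "standalone"
        # precompute per-timestep raw matrices once; the residual loop
        # only multiplies fixed correction matrices around them
        self._R_raw = raw.matrices()
        self._n = len(raw)

    @classmethod
    def from_dataframe(cls, raw_df, reference_df=None,
                       grid_column: str = "percent_cycle",
                       angle_columns: tuple[str, str, str] = (
                           "flexion_deg", "adduction_deg",
                           "internal_rotation_deg")) -> "FrameOrientationModel":
        """Build from pandas DataFrames in the package's CSV column layout."""
        def to_signal(df):
            grid = np.asarray(df[grid_column], dtype=float)
            ang = np.column_stack([np.asarray(df[c], dtype=float)
                                   for c in angle_columns])
            return KinematicSignal(grid, ang)
        ref = to_signal(reference_df) if reference_df is not None else None
        return cls(to_signal(raw_df), ref)

    # -- internal machinery -------------------------------------------------

    def _modified_angles(self, params: np.ndarray) -> np.ndarray:
        """Corrected Cardan angles for a flat 6-parameter vector."""
        C_f = cardan_to_matrix(params[:3])
        C_t = cardan_to_matrix(params[3:])
        return batch_matrix_to_cardan(C_f.T @ self._R_raw @ C_t)

    def _residuals(self, params: np.ndarray, lam: float) -> np.ndarray:
        mod = self._modified_angles(params)
        scale = 1.0 / math.sqrt(self._n)
        if self.mode == "align":
            res = (mod - self.reference.angles).ravel() * scale
        else:
            res = mod[:, 1:3].ravel() * scale
        if lam > 0:
            pen = (mod[:, 0] - self.raw.angles[:, 0]) * (scale * math.sqrt(lam))
            res = np.concatenate([res, pen])
        return res

    def _exact_cost(self, params: np.ndarray, lam: float) -> float:
        mod = self._modified_angles(params)
        if self.mode == "align":
            diff = mod - self.reference.angles
            cost = float(np.sum(np.sqrt(np.mean(diff ** 2, axis=0))))
        else:
            cost = float(np.sum(np.sqrt(np.mean(mod[:, 1:3] ** 2, axis=0))))
        if lam > 0:
            d1 = mod[:, 0] - self.raw.angles[:, 0]
            cost += lam * float(np.sqrt(np.mean(d1 ** 2)))
        return cost

    def _polish(self, x: np.ndarray, lam: float, bound: float | None,
                settings: OptimisationSettings) -> tuple[np.ndarray, int]:
        """Bounded Nelder-Mead refinement of the exact sum-of-RMS cost.

        The polish is deliberately *local*: it is boxed to +-10 deg around
        its start so that it refines the current basin instead of drifting
        along the near-flat joint x-rotation direction of flexion-dominant
        signals (the exact cost is non-smooth at zero residual, hence a
        derivative-free method).
        """
        lo, hi = x - 10.0, x + 10.0
        if bound is not None:
            lo, hi = np.maximum(lo, -bound), np.minimum(hi, bound)
        nm = minimize(self._exact_cost, x, args=(lam,),
                      method="Nelder-Mead", bounds=list(zip(lo, hi)),
                      options={"maxiter": settings.max_iterations * 8,
                               "maxfev": settings.max_iterations * 8,
                               "xatol": 1e-12, "fatol": settings.tolerance})
        if nm.fun < self._exact_cost(x, lam):
            return np.asarray(nm.x, dtype=float), int(nm.nfev)
        return x, int(nm.nfev)

    def _tibia_rotated(self, x: np.ndarray, delta: float,
                       bound: float | None) -> np.ndarray | None:
        """Parameters with the tibial correction post-rotated about x."""
        Rx = elementary_rotation(_X_AXIS, delta)
        try:
            tib = matrix_to_cardan(
                compose(cardan_to_matrix(x[3:]), Rx)).as_array()
        except Exception:
            return None
        p = np.concatenate([x[:3], tib])
        if bound is not None and np.any(np.abs(p) > bound):
            return None
        return p

    def _tibia_valley_candidates(self, x: np.ndarray, lam: float,
                                 bound: float | None,
                                 n_candidates: int = 4
                                 ) -> tuple[list[np.ndarray], int]:
        """Candidate solutions along tibial x-rotations of the correction.

        The inequivalent basins of the standalone cost lie along post-
        rotations of the *tibial* correction about the flexion axis
        (x-rotations of the femoral correction only shift the flexion
        component and are exactly cost-neutral; tibial rotations by 180
        deg mirror the non-dominant components and repeat the cost).
        Scanning one 180-deg fundamental domain therefore visits every
        distinct basin; the best few scan minima are refined and returned
        as polish starts.
        """
        def cost_at(delta: float) -> float:
            p = self._tibia_rotated(x, float(delta), bound)
            return self._exact_cost(p, lam) if p is not None else np.inf

        deltas = np.arange(-88.5, 90.1, 1.5)
        vals = np.array([cost_at(d) for d in deltas])
        nfev = deltas.size
        idx = [i for i in range(len(deltas))
               if np.isfinite(vals[i])
               and vals[i] <= vals[i - 1 if i > 0 else -1]
               and vals[i] <= vals[(i + 1) % len(deltas)]]
        idx.sort(key=lambda i: vals[i])
        out: list[np.ndarray] = []
        from scipy.optimize import minimize_scalar
        for i in idx[:n_candidates]:
            d0 = float(deltas[i])
            r = minimize_scalar(cost_at, bounds=(d0 - 1.5, d0 + 1.5),
                                method="bounded", options={"xatol": 1e-12})
            nfev += int(r.nfev)
            d = float(r.x) if r.fun <= vals[i] else d0
            p = self._tibia_rotated(x, d, bound)
            if p is not None:
                out.append(p)
        return out, nfev

    def _canonicalise_mirror(self, x: np.ndarray, lam: float,
                             bound: float | None) -> np.ndarray:
        """Pick the mirror branch with the smaller tibial correction.

        Rotating the tibial correction by 180 deg about x negates the
        non-dominant components and leaves the standalone cost exactly
        unchanged; the branch whose tibial correction is the smaller
        rotation is reported, keeping corrections in the small-rotation
        regime and making independently optimised datasets directly
        comparable.
        """
        alt = self._tibia_rotated(x, 180.0, bound)
        if alt is None:
            return x

        def geodesic(params3: np.ndarray) -> float:
            R = cardan_to_matrix(params3)
            c = (float(np.trace(R)) - 1.0) / 2.0
            return math.degrees(math.acos(min(1.0, max(-1.0, c))))

        return alt if geodesic(alt[3:]) < geodesic(x[3:]) else x

    def _gauge_fix_flexion(self, x: np.ndarray,
                           bound: float | None) -> tuple[np.ndarray, int]:
        """Resolve the exact femoral flat direction against raw flexion.

        Post-rotating the femoral correction about x shifts only the
        flexion component of the corrected signal and is exactly
        cost-neutral, so the reported representative is chosen to keep
        the corrected flexion as close as possible to the raw flexion
        signal (1-D scan plus bounded refinement).
        """
        raw_flex = self.raw.angles[:, 0]

        def params_at(delta: float) -> np.ndarray | None:
            Rx = elementary_rotation(_X_AXIS, delta)
            try:
                fem = matrix_to_cardan(
                    compose(cardan_to_matrix(x[:3]), Rx)).as_array()
            except Exception:
                return None
            p = np.concatenate([fem, x[3:]])
            if bound is not None and np.any(np.abs(p) > bound):
                return None
            return p

        def flex_dev(delta: float) -> float:
            p = params_at(float(delta))
            if p is None:
                return np.inf
            mod = self._modified_angles(p)
            return float(np.sqrt(np.mean((mod[:, 0] - raw_flex) ** 2)))

        deltas = np.arange(-177.5, 180.1, 2.5)
        vals = np.array([flex_dev(d) for d in deltas])
        nfev = deltas.size
        if not np.any(np.isfinite(vals)):
            return x, nfev
        d0 = float(deltas[int(np.nanargmin(vals))])
        from scipy.optimize import minimize_scalar
        r = minimize_scalar(flex_dev, bounds=(d0 - 2.5, d0 + 2.5),
                            method="bounded", options={"xatol": 1e-12})
        nfev += int(r.nfev)
        d = float(r.x) if r.fun <= vals.min() else d0
        p = params_at(d)
        return (p if p is not None else x), nfev

    def _single_fit(self, x0: np.ndarray,
                    settings: OptimisationSettings) -> tuple[np.ndarray, int]:
        lam = settings.flexion_penalty_weight
        bound = settings.max_correction_deg
        if bound is None:
            ls = least_squares(
                self._residuals, x0, args=(lam,), method="lm",
                xtol=1e-12, ftol=min(settings.tolerance, 1e-12), gtol=1e-12,
                max_nfev=settings.max_iterations * 7)
        else:
            ls = least_squares(
                self._residuals, x0, args=(lam,), method="trf",
                bounds=(-bound, bound),
                xtol=1e-12, ftol=min(settings.tolerance, 1e-12), gtol=1e-12,
                max_nfev=settings.max_iterations)
        nfev = int(ls.nfev)
        best = np.asarray(ls.x, dtype=float)
        if self.mode == "standalone":
            # alternate the tibial valley scan with local polishes of its
            # best candidates until the exact cost stops improving; a
            # basin switch must improve the cost by a resolvable margin so
            # that rounding noise can never flip the selection
            for _ in range(4):
                before = self._exact_cost(best, lam)
                cands, n0 = self._tibia_valley_candidates(best, lam, bound)
                nfev += n0
                polished = []
                for p in [best] + cands:
                    q, n1 = self._polish(p, lam, bound, settings)
                    nfev += n1
                    polished.append(q)
                for q in polished:
                    if (self._exact_cost(best, lam)
                            - self._exact_cost(q, lam) > 1e-9):
                        best = q
                if before - self._exact_cost(best, lam) < settings.tolerance:
                    break
            best = self._canonicalise_mirror(best, lam, bound)
            if lam == 0.0:
                # with an active flexion penalty the femoral direction is
                # no longer flat and needs no gauge choice
                best, n2 = self._gauge_fix_flexion(best, bound)
                nfev += n2
        else:
            best, n1 = self._polish(best, lam, bound, settings)
            nfev += n1
        return best, nfev

    def _detect_flat_direction(self, params: np.ndarray,
                               settings: OptimisationSettings) -> tuple[bool, str]:
        """Probe the analytic near-degeneracy of the standalone cost.

        On a pure hinge, post-multiplying *both* corrections by the same
        rotation about the hinge (x) axis leaves the corrected signal's
        non-dominant components untouched, so the cost is flat along that
        direction. The probe rotates both corrections by a sweep of x-axis
        angles and reports degeneracy when the cost stays within the
        convergence tolerance.
        """
        lam = settings.flexion_penalty_weight
        base = self._exact_cost(params, lam)
        C_f = cardan_to_matrix(params[:3])
        C_t = cardan_to_matrix(params[3:])
        max_change = 0.0
        for delta in (-10.0, -5.0, -1.0, 1.0, 5.0, 10.0):
            Rx = elementary_rotation(_X_AXIS, delta)
            try:
                p = np.concatenate([
                    matrix_to_cardan(compose(C_f, Rx)).as_array(),
                    matrix_to_cardan(compose(C_t, Rx)).as_array()])
                change = abs(self._exact_cost(p, lam) - base)
            except Exception:
                return False, ""
            max_change = max(max_change, change)
        if max_change < settings.tolerance:
            return True, (
                "flat direction detected: rotating both frame corrections "
                "jointly about the x (flexion) axis changes the cost by "
                f"< {settings.tolerance:g} deg (max observed change "
                f"{max_change:.3g} deg); the fitted correction is one of a "
                "family of equivalent solutions. Consider a flexion "
                "penalty or a correction bound to pin it down.")
        return False, ""

    # -- public API ---------------------------------------------------------

    def fit(self, settings: OptimisationSettings | None = None,
            **kwargs) -> FrameOrientationResults:
        """Fit the frame corrections.

        Accepts either a prebuilt :class:`OptimisationSettings` or keyword
        overrides of its fields. The mode is taken from the model (set by
        whether a reference was supplied) and cannot disagree with the
        settings.
        """
        if settings is None:
            kwargs.setdefault("mode", self.mode)
            settings = OptimisationSettings(**kwargs)
        elif kwargs:
            settings = replace(settings, **kwargs)
        if settings.mode != self.mode:
            raise ValueError(
                f"settings.mode={settings.mode!r} but the model was built "
                f"for {self.mode!r} (reference "
                f"{'supplied' if self.reference is not None else 'absent'})")

        lam = settings.flexion_penalty_weight
        x0 = np.zeros(6)
        cost_initial = self._exact_cost(x0, lam)

        starts = [x0]
        if settings.restarts > 1:
            rng = np.random.default_rng(settings.seed)
            spread = settings.max_correction_deg or 30.0
            for _ in range(settings.restarts - 1):
                starts.append(rng.uniform(-spread, spread, size=6))

        # a later start replaces the incumbent only when it wins by a
        # resolvable margin, so ties (flat optima) resolve deterministically
        # in favour of the identity start
        best_x, best_cost, total_nfev = x0, cost_initial, 0
        first = True
        for start in starts:
            x, nfev = self._single_fit(np.asarray(start, dtype=float),
                                       settings)
            total_nfev += nfev
            c = self._exact_cost(x, lam)
            if first and c <= best_cost:
                best_x, best_cost, first = x, c, False
            elif best_cost - c > 1e-9:
                best_x, best_cost = x, c

        correction = FrameCorrection.from_params(best_x)
        modified = reorient_signal(self.raw, correction)
        converged = bool(best_cost <= cost_initial + settings.tolerance)
        degenerate, message = (False, "")
        if self.mode == "standalone":
            degenerate, message = self._detect_flat_direction(best_x, settings)
        return FrameOrientationResults(
            correction=correction,
            modified=modified,
            cost_initial=cost_initial,
            cost_final=best_cost,
            converged=converged,
            n_iterations=total_nfev,
            degenerate_warning=degenerate,
            degenerate_message=message,
            mode=self.mode,
            settings=settings,
        )


# ---------------------------------------------------------------------------
# functional wrappers

def optimise_align(raw: KinematicSignal, reference: KinematicSignal,
                   settings: OptimisationSettings | None = None,
                   **kwargs) -> FrameOrientationResults:
    """Fit frame corrections that align ``raw`` to ``reference``."""
    if settings is None and "mode" not in kwargs:
        kwargs["mode"] = "align"
    return FrameOrientationModel(raw, reference).fit(settings, **kwargs)


def optimise_standalone(raw: KinematicSignal,
                        settings: OptimisationSettings | None = None,
                        **kwargs) -> FrameOrientationResults:
    """Fit frame corrections minimising the non-dominant components."""
    if settings is None and "mode" not in kwargs:
        kwargs["mode"] = "standalone"
    return FrameOrientationModel(raw).fit(settings, **kwargs)


def correction_discrepancy_deg(a: FrameCorrection,
                               b: FrameCorrection) -> float:
    """Largest relative-rotation angle between two corrections, degrees.

    For each segment, measures the geodesic angle of A B^-1 on the
    rotation group; returns the worse of the femoral and tibial values.
    Zero means the two corrections are the same physical rotation even if
    their Cardan angles differ.
    """
    out = 0.0
    for Ra, Rb in zip(a.matrices(), b.matrices()):
        rel = Ra @ Rb.T
        c = (float(np.trace(rel)) - 1.0) / 2.0
        out = max(out, math.degrees(math.acos(min(1.0, max(-1.0, c)))))
    return out
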