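# Methods

## Model

A joint's rotational kinematics over one activity cycle are represented
as a time series of intrinsic X-Y-Z Cardan triplets `(α, β, γ)` in
degrees — flexion/extension, ab/adduction, int/external rotation — i.e.
the rotation matrix factorisation

```
R = R(x̂, α) · R(ŷ, β) · R(ẑ, γ)
```

with active rotations acting on column vectors. This is the matrix form
of the Grood–Suntay joint convention for the orientation of the distal
(tibial) frame relative to the proximal (femoral) frame. Angles are
degrees at every public boundary and radians internally; the
decomposition takes the unique branch `β ∈ (−90°, 90°)` via
`β = asin(R₁₃)` and `atan2` for `α, γ`. Configurations within
`gimbal_tol_deg` (default 1e-6°) of `|β| = 90°` raise a loud
`GimbalLockError` naming the offending timestep — flexion-dominant joint
signals never legitimately approach the singularity, so silence would
mask corrupt input.

The core assumption is rigidity: measured ("raw") and ideal segment
frames are both fixed to the same rigid segment, so their orientation
difference is a *constant* rotation per segment. Fitting the pair of
constant corrections `(C_f, C_t)` in

```
R_mod(t) = C_f⁻¹ · R_raw(t) · C_t
```

can therefore undo any pure frame-orientation disagreement. Soft-tissue
artefact, which breaks rigidity, is out of scope.

## Cost functions and optimiser

Two printed costs are supported (both in degrees, both dividing by the
number of samples N inside the mean):

* align: `Σᵢ₌₁..₃ RMSEᵢ(modified, reference)`;
* standalone: `RMS₂(modified) + RMS₃(modified)`.

An optional penalty `λ · RMSE₁(modified, raw)` (default λ = 0) keeps the
corrected flexion close to the measured one when its absolute values are
clinically meaningful, and a box bound `max_correction_deg` can restrict
the correction magnitude.

The printed costs are sums of root-mean-squares, not sums of squares, so
the fit proceeds in two stages: a Levenberg–Marquardt pass on the stacked
per-sample residuals (whose squared sum is a monotone surrogate sharing
the zero-cost minimiser), then a bounded Nelder–Mead refinement of the
exact cost, boxed to ±10° around the least-squares solution so it refines
the same basin. Initialisation is at the identity correction, which keeps
the fit in the small-correction regime typical of segment-frame errors;
optional seeded multistart (`restarts > 1`) draws additional starting
points uniformly within ±`max_correction_deg` (±30° if unbounded).
Convergence is declared when the cost change falls below `tolerance`
(default 1e-10°) within `max_iterations` (default 500); non-convergence
is flagged on the results object, not raised.

### Flat directions of the standalone cost

The standalone cost has exact and near-exact invariances that a naive
optimiser handles badly:

* **Femoral x-rotation (exact, always).** Post-multiplying `C_f` by any
  rotation about x premultiplies `R_mod(t)` by its inverse, which changes
  only the first row-decomposed component (flexion): `β` and `γ` are
  computed from the first row of `R_mod`, which is untouched. The
  standalone cost is therefore *exactly* constant along this direction.
  The reported representative is chosen by a cost-neutral gauge rule:
  the femoral x-rotation that brings the corrected flexion closest (in
  RMSE) to the raw flexion. With an active flexion penalty the direction
  is no longer flat and needs no gauge choice.
* **Tibial x-rotation (structures the basins).** Post-rotating `C_t`
  about x mixes the non-dominant components; distinct local basins of the
  cost lie along this direction, and rotating by 180° mirrors `(β, γ) →
  (−β, −γ)` at exactly equal cost. The fit therefore scans one 180°
  fundamental domain of tibial x-rotations, polishes each scan minimum,
  and accepts a basin switch only when it improves the cost by a
  resolvable margin (1e-9°), so floating-point noise can never flip the
  selection. The mirror branch is canonicalised to the smaller tibial
  correction, keeping independently optimised datasets directly
  comparable.
* **Pure hinge (data degeneracy).** On a hinge signal rotating *both*
  corrections jointly about x is cost-neutral. After every standalone
  fit this direction is probed explicitly (joint x-sweeps of ±1°…±10°);
  if the cost varies by less than `tolerance` the result carries a
  degeneracy warning naming the remedy (flexion penalty or correction
  bound).

Align mode has none of these degeneracies for generic references; it uses
the plain LM + local-polish path.

## Synthetic data generator

The generator emulates the bench conditions the method targets: cycles of
flexion-dominant daily activities measured through differently oriented
segment frames, without soft-tissue artefact. Defaults:

* **walking** — two-peak flexion curve (offset 26°, 22° fundamental, 9°
  second harmonic), range ≈ 4–57°;
* **stair descent** — single broad peak, ≈ 6–90°;
* **sit–stand–sit** — flexed at both ends, extended mid-cycle, ≈ 10–90°;
* frontal component: 3° sinusoid; transverse: 5° sinusoid (phase-shifted,
  zeroed at cycle start), values chosen as physiologically plausible
  non-dominant knee motion. All coefficients are overridable.

Misalignment injection is the exact algebraic inverse of the correction
operation (`R_raw = M_f · R_ideal · M_t⁻¹`), so reorienting by the
injected pair restores the ideal signal to machine precision — the
ground truth every optimisation test is scored against. Optional Gaussian
noise is added in angle space (the claims under test concern frame
misalignment, not sensor error models). `make_trial_set` draws per-subject
misalignments uniformly in ±15° per angle by default, the magnitude
regime of segment-frame disagreement the experiments model.

What the generator does **not** emulate: soft-tissue artefact,
sensor-fusion estimation error, non-rigid marker/sensor motion,
multi-cycle variability. Passing tests therefore demonstrate correctness
of the frame-orientation algebra and optimisation, not robustness to
those real-world effects.

## Evaluation conventions

Per-trial RMSEs are computed first, then summarised as mean ± sample
standard deviation (n−1 denominator; a single trial reports sd = 0 and
`n_trials = 1`). Condition comparisons use two-sided paired t-tests with
a Bonferroni option (`p_bonf = min(1, m·p)`, default m = 2 comparisons
against the unoptimised baseline); verdicts at the 0.05 level are
reported both raw and corrected. A constant nonzero paired difference has
an undefined-variance statistic and is reported as an infinite t with
p = 0; identically zero differences raise an error.

## Experiment sizes and numerical choices

The shipped experiments use 101-sample cycles, six subjects per activity
and three activities — comfortably resolving every effect under test
while keeping the whole suite and the acceptance script fast on a single
CPU. Further choices a maintainer should know:

* cross-talk *removal* is measured on inputs whose genuine non-dominant
  motion is small relative to the injected cross-talk (frontal 1°,
  transverse 1.5° amplitudes); with physiologically larger non-dominant
  motion (the walking defaults) the standalone optimum correctly retains
  that genuine motion as an irreducible floor (≈ 3.9° summed RMS), and a
  percentage-reduction reading would conflate the two;
* signals to be compared must share a cycle grid exactly; resampling is
  a separate, explicit, linear-in-percent-cycle utility — never implicit;
* CSV I/O writes 17 significant digits so write→read round trips are
  exact to < 1e-12°;
* seeded runs are bit-reproducible across process invocations. Within a
  single long-lived process, repeated identical fits agree to solver
  precision (~1e-9°) rather than bit-exactly: NumPy's SIMD reductions may
  group operations differently depending on buffer alignment, and the
  optimiser's stopping decisions can amplify such last-bit differences.

## Known limitations

* Only the intrinsic X-Y-Z sequence is supported; clinical sign
  conventions (left/right side flips) are the caller's responsibility via
  signal metadata.
* One activity cycle per signal; no multi-cycle or multi-subject joint
  optimisation (each signal is fitted independently).
* Standalone mode cannot recover the true flexion offset without a
  reference: the femoral flat direction makes the flexion zero-point a
  convention, fixed here relative to the raw signal.
* Translational kinematics are out of scope.
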