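# Methods

## Model and assumptions

The package implements a two-variable mood–expectation model of bipolar
disorder.  Mood `m` is a single dimensionless trait; expectation `v` and
reality `r` share one arbitrary unit; time is fixed to weeks (all rates are
per week), matching the cycle lengths the model is meant to describe.  The
dynamics are

    dm/dt = η_m (f m + r − v) − k m − k₃ m³
    dv/dt = η_v (f m + r − v)

Assumptions worth making explicit:

* Reality is exogenous — mood never feeds back on actual events, only on
  *perceived* reality `f m + r`.
* The mood learning rate may switch between `η_m⁺` (positive surprise) and
  `η_m⁻` (non-positive surprise).  The switching boundary
  `f m + r − v = 0` is assigned to the minus branch (boundary-inclusive),
  and the vector field is continuous across it: only its derivative jumps.
  Because the field is continuous, sliding solutions cannot occur and
  classical (Carathéodory) solutions suffice.
* The cubic recovery `−k₃ m³` is the only saturation mechanism; without it
  the supra-threshold system would diverge, and with `k = 0` the cyclothymic
  (damped-ringing) regime disappears entirely.
* All six parameters are strictly positive.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| η_m⁺, η_m⁻ | mood learning rates | set via sensitivity ratios | 1/week |
| η_v | expectation learning rate | 0.37 | 1/week |
| f | mood → perceived-reality scale | 0.3 | — |
| k | linear mood recovery | 0.37 | 1/week |
| k₃ | cubic mood recovery | 2.8×10⁻³ | 1/(mood²·week) |

The bifurcation parameter is the mood sensitivity `fη_m`; the Hopf threshold
is `η_v + k`.  `ModelParams.from_ratios(r⁺, r⁻)` sets sensitivities as
multiples of that threshold, which is how regimes are most naturally
specified (0.3–0.9 cyclothymic spectrum, >1 bipolar).  The step-protocol
bias experiment uses the faster set `η_v = k = 1.85`, `k₃ = 0.014`, where
adaptation happens within days rather than months.

## Reality processes

Deterministic realities are piecewise constant with explicit breakpoints
(right-open segments: a query at a jump time returns the new level).  The
stochastic process is a renewal process emulating abrupt life events:
segment levels i.i.d. Normal(0, σ_r²), waiting times lognormal whose
*underlying* normal has mean 1/k_r and s.d. 1/k_r — the log-time moments are
specified directly, not the lognormal's own mean.  Levels are uncorrelated
and realizations are not re-centered per sample; only the population mean is
zero.  Draws come from numpy's PCG64 (`default_rng(seed)`) in fixed-size
chunks, so a seed pins a realization bit-for-bit across platforms.

What the generator does *not* emulate: autocorrelated or heavy-tailed event
streams, diurnal/seasonal structure, and any feedback from mood onto event
frequency.  A green test therefore establishes internal consistency of the
model under its stated event statistics, not realism of the event model
itself.

## Integration

`simulate` uses scipy's explicit Runge–Kutta pairs (RK45 default, DOP853 for
tight-tolerance oracles) with three kinds of restart points:

* reality jumps and intervention times are hard breakpoints (state is
  continuous; `r` or the parameters change);
* with asymmetric learning rates, a terminal root-finding event locates each
  crossing of `f m + r − v = 0`; integration restarts on the other branch at
  the located root.  The post-switch branch is carried explicitly into the
  next arc rather than re-derived from the (numerically ambiguous) sign of
  the surprise at the root, which removes event re-triggering at the
  restart point.  A counter (10⁴ switches per segment) guards pathological
  chatter and points the user to the optional logistic smoothing of the
  switch (`smoothing > 0`, default off, for robustness experiments only).

Defaults: rel_tol 1e−8, abs_tol 1e−10, output every 0.05 weeks — oscillation
periods are 10–20 weeks, so this is comfortably resolved.  Scans reduce to
rel_tol 1e−6 and 0.25-week output to fit compute budgets; the stability
verdicts are insensitive to this (agreement statistics are unchanged at
full tolerance on spot checks).  At exact switching-boundary starts the
branch used for the first arc is chosen from the sign of d(surprise)/dt
(branch-independent there); recorded per-sample branches always follow the
boundary-inclusive-on-minus convention.

## Cycle quantification

Extrema of `m(t)` are located from sign changes of the discrete derivative
on the dense output and refined with a local quadratic; ties resolve to the
earliest time.  Amplitude is the mean |m| at extrema over the assessment
window (default: the second half of the horizon, matching the convention of
the two-parameter scan with horizon 162.5 and window [81.25, 162.5]); the
period is the mean spacing of maxima; convergence requires the last ≤6
extremal amplitudes to agree within 1% relative spread.  Degenerate inputs:
a trajectory with no extrema reports amplitude 0 and converged = False.

The empirical stable/unstable call of the stability scan compares the
mood s.d. against the same statistic for the *critical* model
(`fη_m⁺ = fη_m⁻ = η_v + k`) run under an identical protocol, which makes
the contour level self-calibrating rather than an arbitrary threshold.

The Hopf-threshold bisection classifies a run as oscillatory when the mood
s.d. of the last third of an 800-week run exceeds 0.9× that of the middle
third.  The ratio test distinguishes saturated-or-growing cycles (ratio ≈ 1
or above) from decay (ratio well below 1) without needing an absolute
amplitude floor, which would fail near the threshold where both decay rates
and cycle amplitudes vanish.

## Stability decision table

Per half-plane regimes follow the discriminant/trace boundaries at
`η_v + k ± 2√(η_v k)` and `η_v + k`.  Boundaries are excluded: parameters
within 1e−9 relative of one are reported as *degenerate* rather than
silently classified.  Verdicts: both stable → stable; both unstable →
unstable; node + spiral → the node's stability; stable spiral + unstable
spiral → sign of the summed half-cycle exponents.  For the stable-node +
unstable-node coexistence the verdict is *unstable* (the numerically
observed outcome) but flagged `initial_condition_sensitive`, because
wedge-shaped sets of initial conditions can instead converge; both facts are
surfaced instead of resolved.  Wedge trajectories in node half-planes are
not special-cased; the grid-agreement statistic absorbs them.

## Interventions

* *Antidepressant as mood lift*: at the treatment time, `m` is reset to
  `p ×` (running minimum of `m` so far).  "Reduce the depression to p of its
  lowest value" is read as a reset target, not an increment: the protocol
  treats at the cycle trough, where the running minimum and the current
  depression coincide, so the two readings agree there anyway.
* *Antidepressant as sensitivity increase*: `fη_m⁺` is replaced from the
  event time on.
* *Lithium*: both learning rates scaled by (1 − reduction).

A deliberate finding surfaced by the tests: the mood-lift protocol is
threshold-like, not uniformly monotone.  Light doses (p ≳ 0.5) leave the
next manic episode essentially at its usual time (in fact ~0.1–0.5 weeks
*later*, because the smaller post-reset amplitude climbs more slowly in the
nonlinear regime), while heavy doses advance it sharply.  Dose–response
monotonicity is therefore asserted on the heavy-dose ladder
{0.7, 0.3, 0.1}, with a separate near-invariance check at p = 0.9.

QIDS-SR16 is modelled as `min(27, scale · max(0, −m))`.  The scale is a
config knob (default 1.0) since only the instrument ceiling is fixed; mania
does not register on the QIDS at all.

## Known limitations

* No stochastic forcing inside the ODEs (noise enters only through r(t)),
  no delays, no time-varying parameters, and mania is one-dimensional.
* The near-threshold amplitude law is measured numerically; no weakly
  nonlinear expansion is provided.
* The half-plane stability theory is exact only for the linearized system;
  the full model inherits it empirically through the scan comparison.
* The amplitude power-law check normalizes shape only; absolute amplitudes
  depend on k₃, which is phenomenological.
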