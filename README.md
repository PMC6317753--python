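# moodcycles

A simulator and analyzer for a dynamical-systems model of bipolar disorder
built on the interaction between **mood** and **learned expectation**.  It is
aimed at computational-psychiatry researchers who want a tested, scriptable
implementation of the model: its piecewise-smooth ODE dynamics, its
closed-form stability theory, its limit-cycle (bipolar) regime, and its
medication-intervention protocols.

## The model

Mood `m(t)` (dimensionless) and expectation `v(t)` respond to an external
reality `r(t)` through the *perceived surprise* `f·m + r − v` — reality as
colored by the current mood, minus what was expected:

```
dm/dt = η_m (f·m + r − v) − k·m − k₃·m³
dv/dt = η_v (f·m + r − v)
```

with learning rates `η_m`, `η_v` (1/week), mood-perception scale `f`, and
linear/cubic mood recovery `k`, `k₃`.  The mood learning rate may differ for
positive and negative surprises (`η_m⁺` vs `η_m⁻`, switching across
`f·m + r − v = 0`), which makes the vector field continuous but non-smooth.
Eliminating `v` yields an equivalent Liénard (van der Pol–like) oscillator
forced by *changes* in reality.

Key results the package computes and tests:

* **Eigenvalues & regimes.** Linearizing about the euthymic fixed point gives
  `λ± = (fη_m − η_v − k)/2 ± √Δ/2` with `Δ = (fη_m − η_v − k)² − 4η_v k`.
  The *mood sensitivity* `fη_m` is the bifurcation parameter; each half-plane
  is a stable/unstable node or spiral.
* **Supercritical Hopf bifurcation** at `fη_m = η_v + k`: beyond it mood
  oscillates persistently (the bipolar state), confined by the rectangle
  `(±m*, ±f·m*)` with `m* = √((2fη_m − k)/k₃)`.
* **Asymmetric-sensitivity stability.**  With spirals in both half-planes the
  origin is stable iff
  `π(fη_m⁺−η_v−k)/√(4η_v k−(fη_m⁺−η_v−k)²) + π(fη_m⁻−η_v−k)/√(4η_v k−(fη_m⁻−η_v−k)²) < 0`,
  i.e. iff `f(η_m⁺+η_m⁻) < 2(η_v+k)`; a node dominates a coexisting spiral.
* **Reality processes**: constant, step protocols, and a seeded renewal
  process (Normal levels, lognormal waiting times).
* **Clinical protocols**: QIDS-SR16 scores as rectified negative mood;
  antidepressants as a mood lift or a raised `fη_m⁺`; lithium as a symmetric
  sensitivity reduction.

## Worked example

```python
import numpy as np
from moodcycles import (ModelParams, State, constant_reality, simulate,
                        estimate_cycle, m_star, predict_stability)

# bipolar subject: fη_m = 1.5·(η_v + k), with η_v = k = 0.37/wk, f = 0.3
p = ModelParams.from_ratios(1.5)
print(predict_stability(p).verdict)          # -> unstable

traj = simulate(p, constant_reality(0.0, 300.0), State(m=0.0, v=-1.0), 300.0)
s = estimate_cycle(traj, 0.5, p)
print(f"{s.amplitude:.3f} {s.period:.2f} {m_star(p):.2f}")
# -> 13.031 12.57 25.70
```

The origin is linearly unstable, and the 300-week run settles onto a limit
cycle with mood amplitude 13.0 (safely inside the analytic outer bound
`m* = 25.70`) and period 12.6 weeks — persistent mood cycling under a
perfectly constant reality.  A subthreshold subject
(`ModelParams.from_ratios(0.3)`) instead rings down to the euthymic fixed
point.

## Command line

```bash
moodcycles schema                         # config JSON Schema
moodcycles simulate -c run.yaml -o out    # out.csv + out.report.json
moodcycles linstab --eta-m-plus 3.7 --eta-m-minus 3.7 \
    --eta-v 0.37 --f 0.3 --k 0.37 --k3 2.8e-3   # exit 0 stable / 3 unstable / 4 degenerate
moodcycles scan --reduced -o scan         # two-parameter stability map
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the package's main pipeline from scratch — closed-form stability
verdicts for normal and bipolar parameter sets, the deterministic bipolar
limit-cycle run with amplitude/period extraction against the outer bound, a
seeded random-reality run with QIDS scoring, and the lithium protocol — then
writes the results JSON to `--out`.  Progress and summary numbers go to
stderr.

## Layout

* `model_core` — parameters, state, right-hand sides (first-order and Liénard).
* `reality` — constant / step / seeded stochastic reality processes.
* `integrator` — event-aware piecewise-smooth integration (`simulate`,
  `simulate_linearized`), trajectories.
* `linear_analysis` — eigenvalues, half-plane regimes, half-cycle
  multipliers, overall stability verdicts.
* `limit_cycle` — amplitude/period extraction, outer bound, Hopf-threshold
  bisection, amplitude and stability scans, step-reality bias protocol.
* `clinical` — QIDS scoring and intervention protocols.
* `cli_io` — config schema, CSV/JSON writers, the `moodcycles` CLI.

See `docs/methods.md` for modelling assumptions, numerical choices, and
limitations.
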