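"""Clinical read-outs and medication-intervention protocols.

Depression severity is reported on the QIDS-SR16 scale by rectifying
negative mood: ``score = scale * max(0, -m)``, clipped at the instrument's
ceiling of 27.  Three interventions on a running simulation are modelled:

* antidepressant as a mood elevation — during a depressive episode the mood
  is instantaneously reset to a fraction p of its lowest value so far;
* antidepressant as an increased positive mood sensitivity — f*eta_m_plus
  is raised from the treatment time on;
* lithium as a symmetric sedation — both mood learning rates are scaled
  down by a reduction fraction from the treatment time on.

Each helper wraps :func:`~moodcycles.integrator.simulate` with an
:class:`InterventionSchedule`; applied events land in the trajectory's
event log.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .integrator import SolverOptions, Trajectory, simulate
from .model_core import ModelParams, State
from .reality import RealityRealization, constant_reality

__all__ = [
    "QIDSConfig",
    "qids_series",
    "attach_qids",
    "InterventionEvent",
    "InterventionSchedule",
    "antidepressant_mood_shift",
    "antidepressant_sensitivity",
    "lithium_sensitivity_reduction",
    "first_mood_maximum_after",
    "first_qids_peak_after",
]

KINDS = ("mood_shift_fraction", "set_positive_sensitivity", "scale_both_sensitivities")


@dataclass(frozen=True)
class QIDSConfig:
    """Mood-to-QIDS mapping: positive scale factor and score ceiling (27)."""

    scale: float = 1.0
    clip_max: float = 27.0

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("scale must be positive")


def qids_series(traj: Trajectory, config: QIDSConfig | None = None) -> np.ndarray:
    """QIDS score ``min(clip_max, scale * max(0, -m))`` along a trajectory.

    Zero whenever mood is non-negative; only depression registers on the
    instrument.
    """
    config = config or QIDSConfig()
    score = config.scale * np.maximum(0.0, -traj.m)
    if config.clip_max is not None:
        score = np.minimum(score, config.clip_max)
    return score


def attach_qids(traj: Trajectory, config: QIDSConfig | None = None) -> Trajectory:
    """Fill the trajectory's qids column in place and return it."""
    traj.qids = qids_series(traj, config)
    return traj


@dataclass(frozen=True)
class InterventionEvent:
    """A single scheduled intervention.

    kind:
      mood_shift_fraction      — magnitude p in (0, 1): reset m to
                                 p * (running minimum of m so far);
      set_positive_sensitivity — magnitude is the new f*eta_m_plus;
      scale_both_sensitivities — magnitude multiplies both learning rates.
    """

    time: float
    kind: str
    magnitude: float

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown intervention kind {self.kind!r}; expected one of {KINDS}")
        if self.kind == "mood_shift_fraction" and not (0 < self.magnitude < 1):
            raise ValueError("mood_shift_fraction magnitude must lie in (0, 1)")
        if self.kind == "scale_both_sensitivities" and not self.magnitude > 0:
            raise ValueError("sensitivity scale factor must be positive")

    def apply(self, params: ModelParams, y: np.ndarray, running_min_m: float):
        """Apply to (params, state); returns (params, state, log info)."""
        info = {"kind": self.kind, "magnitude": self.magnitude}
        if self.kind == "mood_shift_fraction":
            if y[0] >= 0:
                warnings.warn(
                    "antidepressant mood shift applied outside a depressive episode "
                    f"(m = {y[0]:.4g} at t = {self.time:.4g})",
                    stacklevel=2,
                )
            target = self.magnitude * running_min_m
            info["m_before"], info["m_after"] = float(y[0]), float(target)
            y = np.array([target, y[1]])
            return params, y, info
        if self.kind == "set_positive_sensitivity":
            if self.magnitude <= params.f_eta_m_plus:
                warnings.warn(
                    "antidepressant sensitivity event does not increase f*eta_m_plus",
                    stacklevel=2,
                )
            return params.with_sensitivities(f_eta_m_plus=self.magnitude), y, info
        # scale_both_sensitivities
        return params.scaled_sensitivities(self.magnitude), y, info


@dataclass(frozen=True)
class InterventionSchedule:
    """Time-ordered collection of intervention events."""

    events: tuple[InterventionEvent, ...]

    def __init__(self, events):
        evs = tuple(sorted(events, key=lambda e: e.time))
        object.__setattr__(self, "events", evs)

    def __iter__(self):
        return iter(self.events)

    def __len__(self):
        return len(self.events)


def _default_bipolar(params: ModelParams | None) -> ModelParams:
    return params if params is not None else ModelParams.from_ratios(1.5)


def antidepressant_mood_shift(
    params: ModelParams | None = None,
    time: float = 9.2,
    fraction: float = 0.7,
    *,
    reality: RealityRealization | None = None,
    init: State = State(0.0, -1.0),
    horizon: float = 60.0,
    opts: SolverOptions | None = None,
) -> Trajectory:
    """Bipolar run treated with an antidepressant modelled as a mood lift.

    At ``time`` (weeks; default 9.2, inside the first depressive episode of
    the canonical bipolar run) the depression is cut to ``fraction`` of its
    lowest value so far.  Smaller fractions are higher doses; high doses
    phase-advance the cycle and bring the next manic episode forward.
    """
    params = _default_bipolar(params)
    reality = reality or constant_reality(0.0, horizon)
    sched = InterventionSchedule([InterventionEvent(time, "mood_shift_fraction", fraction)])
    return attach_qids(simulate(params, reality, init, horizon, opts, sched))


def antidepressant_sensitivity(
    params: ModelParams | None = None,
    time: float = 9.2,
    new_f_eta_m_plus: float | None = None,
    *,
    reality: RealityRealization | None = None,
    init: State = State(0.0, -1.0),
    horizon: float = 60.0,
    opts: SolverOptions | None = None,
) -> Trajectory:
    """Bipolar run with the positive mood sensitivity raised at ``time``.

    Models the alternative antidepressant mechanism: stronger response to
    positive surprises.  Larger doses give earlier, larger, faster cycles.
    """
    params = _default_bipolar(params)
    if new_f_eta_m_plus is None:
        new_f_eta_m_plus = 2.25 * (params.eta_v + params.k)
    reality = reality or constant_reality(0.0, horizon)
    sched = InterventionSchedule(
        [InterventionEvent(time, "set_positive_sensitivity", new_f_eta_m_plus)]
    )
    return attach_qids(simulate(params, reality, init, horizon, opts, sched))


def lithium_sensitivity_reduction(
    params: ModelParams | None = None,
    time: float = 27.1,
    reduction_fraction: float = 0.2,
    *,
    reality: RealityRealization | None = None,
    init: State = State(0.0, -1.0),
    horizon: float = 110.0,
    opts: SolverOptions | None = None,
) -> Trajectory:
    """Bipolar run sedated by a symmetric sensitivity reduction at ``time``.

    Both learning rates are scaled by ``1 - reduction_fraction`` (default
    20%).  Amplitudes shrink and no mania is induced; a reduction deep
    enough to cross the threshold extinguishes the oscillation entirely.
    """
    if not 0 < reduction_fraction < 1:
        raise ValueError("reduction_fraction must lie in (0, 1)")
    params = _default_bipolar(params)
    reality = reality or constant_reality(0.0, horizon)
    sched = InterventionSchedule(
        [InterventionEvent(time, "scale_both_sensitivities", 1.0 - reduction_fraction)]
    )
    return attach_qids(simulate(params, reality, init, horizon, opts, sched))


def _first_local_max(t: np.ndarray, x: np.ndarray, t0: float, min_value: float):
    from .limit_cycle import _refine_extremum

    sign = np.sign(np.diff(x))
    for i in range(1, len(sign)):
        if t[i] <= t0:
            continue
        if sign[i - 1] > 0 and sign[i] < 0:
            tv, xv = _refine_extremum(t, x, i)
            if tv > t0 and xv > min_value:
                return tv, xv
    raise ValueError(f"no local maximum above {min_value} found after t = {t0}")


def first_mood_maximum_after(
    traj: Trajectory, t0: float, min_value: float = 0.0
) -> tuple[float, float]:
    """Time and value of the first local mood maximum after t0 exceeding
    ``min_value`` (default 0: a manic peak, not the reset artifact of a
    mood-shift treatment).  Quadratic refinement on the dense grid.
    """
    return _first_local_max(traj.times, traj.m, t0, min_value)


def first_qids_peak_after(traj: Trajectory, t0: float, config: QIDSConfig | None = None):
    """Time and value of the first strictly positive local QIDS maximum
    (depression peak) after t0.  Pass the preceding manic-peak time as t0 to
    time the next depressive episode.
    """
    return _first_local_max(traj.times, qids_series(traj, config), t0, 0.0)
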