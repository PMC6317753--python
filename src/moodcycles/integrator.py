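"""Event-aware integration of the piecewise-smooth mood–expectation system.

The vector field is continuous but its Jacobian jumps across the switching
line ``f*m + r - v = 0`` when the mood learning rates are asymmetric, and
the forcing r(t) itself jumps at reality events.  Naive adaptive stepping
across those surfaces degrades the local error model, so the integrator:

* restarts at every reality jump and intervention time (hard breakpoints;
  the state is continuous, only r or the parameters change), and
* when the learning rates are asymmetric, integrates each smooth branch
  with a terminal root-finding event on the surprise and restarts on the
  other branch at the located crossing.

Within a branch the field is smooth, so scipy's Dormand–Prince pairs
(RK45/DOP853 via ``solve_ivp``) apply with their nominal error control.
Sliding along the switching line cannot occur (the field is continuous
across it), but a chatter counter guards pathological configurations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model_core import ModelParams, State, _logistic, lienard_rhs, np_surprise, surprise
from .reality import RealityRealization, constant_reality

__all__ = [
    "SolverOptions",
    "Trajectory",
    "DivergenceError",
    "ChatterError",
    "simulate",
    "simulate_linearized",
    "simulate_lienard",
]

_MAX_SWITCHES_PER_SEGMENT = 10_000


class DivergenceError(RuntimeError):
    """Raised when the state stops being finite; carries the divergence time."""

    def __init__(self, time: float):
        self.time = time
        super().__init__(f"integration diverged (non-finite state) near t = {time:.6g} weeks")


class ChatterError(RuntimeError):
    """Raised when branch switching exceeds the chatter bound."""

    def __init__(self, time: float):
        self.time = time
        super().__init__(
            f"excessive branch switching near t = {time:.6g} weeks; "
            "consider the logistic smoothing option (smoothing > 0)"
        )


@dataclass(frozen=True)
class SolverOptions:
    """Solver controls.

    Defaults resolve oscillation periods of tens of weeks cheaply:
    rel_tol 1e-8, abs_tol 1e-10, dense output every 0.05 weeks.
    """

    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    max_step: float = math.inf
    output_grid_spacing: float = 0.05
    method: str = "RK45"

    def __post_init__(self) -> None:
        if not (self.rel_tol > 0 and self.abs_tol > 0 and self.output_grid_spacing > 0):
            raise ValueError("tolerances and grid spacing must be positive")


@dataclass
class Trajectory:
    """Time-gridded record of a simulation.

    ``branch`` holds the active learning-rate branch at each sample under
    the boundary-inclusive-on-minus convention: +1 where the surprise is
    positive, -1 otherwise.  ``qids`` stays None until filled by the
    clinical module.
    """

    times: np.ndarray
    m: np.ndarray
    v: np.ndarray
    r: np.ndarray
    branch: np.ndarray
    event_log: list[dict] = field(default_factory=list)
    params: ModelParams | None = None
    qids: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.m) == len(self.v) == len(self.r) == len(self.branch) == n):
            raise ValueError("trajectory arrays must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def surprise(self) -> np.ndarray:
        if self.params is None:
            raise ValueError("trajectory carries no params")
        return np_surprise(self.m, self.v, self.r, self.params.f)

    def window(self, t0: float, t1: float | None = None) -> "Trajectory":
        """Sub-trajectory with t in [t0, t1]."""
        t1 = self.times[-1] if t1 is None else t1
        mask = (self.times >= t0) & (self.times <= t1)
        return Trajectory(
            self.times[mask],
            self.m[mask],
            self.v[mask],
            self.r[mask],
            self.branch[mask],
            event_log=[e for e in self.event_log if t0 <= e["time"] <= t1],
            params=self.params,
            qids=None if self.qids is None else self.qids[mask],
        )

    def to_dataframe(self) -> pd.DataFrame:
        qids = np.full(len(self.times), np.nan) if self.qids is None else self.qids
        return pd.DataFrame(
            {
                "time": self.times,
                "m": self.m,
                "v": self.v,
                "r": self.r,
                "branch": self.branch,
                "qids": qids,
            }
        )


def _output_grid(t0: float, horizon: float, spacing: float) -> np.ndarray:
    n = int(round((horizon - t0) / spacing))
    if abs(t0 + n * spacing - horizon) < 1e-9 * max(1.0, abs(horizon)) and n >= 1:
        return t0 + spacing * np.arange(n + 1)
    grid = np.arange(t0, horizon, spacing)
    return np.append(grid, horizon)


def _branch_sign(g: float, gdot: float) -> int:
    """Active branch from the surprise and (at the boundary) its trend.

    At g = 0 the field is branch-independent, so the immediate future sign
    of g decides which branch the next smooth arc belongs to.
    """
    if g > 0:
        return 1
    if g < 0:
        return -1
    return 1 if gdot > 0 else -1


def simulate(
    params: ModelParams,
    reality: RealityRealization | Callable[[float], float],
    init: State,
    horizon: float,
    opts: SolverOptions | None = None,
    interventions=None,
    *,
    drop_cubic: bool = False,
    smoothing: float = 0.0,
) -> Trajectory:
    """Integrate the mood–expectation system and sample it on a fixed grid.

    Parameters
    ----------
    reality
        A :class:`~moodcycles.reality.RealityRealization` (jumps become hard
        breakpoints) or a smooth callable ``r(t)`` (no breakpoints).
    interventions
        Optional :class:`~moodcycles.clinical.InterventionSchedule`; events
        modify the state or the parameters at their scheduled times.

    Raises
    ------
    DivergenceError
        If the state stops being finite; the message names the time.
    ChatterError
        If branch switching exceeds the chatter bound.
    """
    opts = opts or SolverOptions()
    t0 = init.t
    if not horizon > t0:
        raise ValueError("horizon must exceed the initial time")

    smooth_reality = callable(reality) and not isinstance(reality, RealityRealization)
    r_of = reality if smooth_reality else reality.__call__

    event_log: list[dict] = []
    breakpoints: list[tuple[float, str, object]] = []
    if not smooth_reality:
        for tj in reality.jumps_within(t0, horizon):
            breakpoints.append((float(tj), "reality_jump", None))
    iv_events = [] if interventions is None else list(interventions)
    for ev in iv_events:
        if not (t0 < ev.time < horizon):
            raise ValueError(f"intervention time {ev.time} outside ({t0}, {horizon})")
        breakpoints.append((float(ev.time), "intervention", ev))
    breakpoints.sort(key=lambda b: b[0])

    grid = _output_grid(t0, horizon, opts.output_grid_spacing)
    m_out = np.empty_like(grid)
    v_out = np.empty_like(grid)
    gp = 0  # next grid index to fill

    cur = params
    t = t0
    y = np.array([init.m, init.v], dtype=float)
    m_out[0], v_out[0] = y
    gp = 1
    running_min_m = init.m

    segments = breakpoints + [(horizon, "end", None)]
    for seg_end, seg_kind, seg_payload in segments:
        # integrate over [t, seg_end], restarting at branch switches
        n_switch = 0
        pending_branch: int | None = None  # branch fixed by a located crossing
        while t < seg_end - 1e-13 * max(1.0, abs(seg_end)):
            r_now = float(r_of(t))
            g = surprise(y[0], y[1], r_now, cur.f)
            gdot = cur.f * (-cur.k * y[0] - (0 if drop_cubic else cur.k3 * y[0] ** 3))
            need_events = (not cur.symmetric) and smoothing == 0.0
            if pending_branch is not None:
                branch = pending_branch
                pending_branch = None
            else:
                branch = _branch_sign(g, gdot)
            eta = cur.eta_m_plus if branch > 0 else cur.eta_m_minus
            p = cur  # close over current params

            def f_rhs(tt, yy, eta=eta, p=p):
                s = p.f * yy[0] + float(r_of(tt)) - yy[1]
                if smoothing > 0.0:
                    w = _logistic(s / smoothing)
                    e = p.eta_m_minus + (p.eta_m_plus - p.eta_m_minus) * w
                else:
                    e = eta
                dm = e * s - p.k * yy[0]
                if not drop_cubic:
                    dm -= p.k3 * yy[0] ** 3
                return [dm, p.eta_v * s]

            events = None
            if need_events:

                def crossing(tt, yy, p=p):
                    return p.f * yy[0] + float(r_of(tt)) - yy[1]

                crossing.terminal = True
                crossing.direction = -branch
                events = [crossing]

            sol = solve_ivp(
                f_rhs,
                (t, seg_end),
                y,
                method=opts.method,
                rtol=opts.rel_tol,
                atol=opts.abs_tol,
                max_step=opts.max_step,
                dense_output=True,
                events=events,
            )
            if not np.all(np.isfinite(sol.y)):
                raise DivergenceError(sol.t[-1])
            if not sol.success and sol.status != 1:
                raise DivergenceError(sol.t[-1])

            t_arc_end = sol.t[-1]
            while gp < len(grid) and grid[gp] <= t_arc_end + 1e-12:
                ym, yv = sol.sol(min(grid[gp], t_arc_end))
                m_out[gp], v_out[gp] = ym, yv
                gp += 1
            arc_min = float(np.min(sol.sol(np.linspace(t, t_arc_end, 64))[0])) if t_arc_end > t else y[0]
            running_min_m = min(running_min_m, arc_min, float(sol.y[0, -1]))

            if sol.status == 1:  # branch switch located
                t = float(sol.t_events[0][0])
                y = sol.y_events[0][0].copy()
                pending_branch = -branch
                n_switch += 1
                event_log.append({"time": t, "type": "switch", "to_branch": -branch})
                if n_switch > _MAX_SWITCHES_PER_SEGMENT:
                    raise ChatterError(t)
            else:
                t = seg_end
                y = sol.y[:, -1].copy()

        if seg_kind == "reality_jump":
            event_log.append({"time": seg_end, "type": "reality_jump", "level": float(r_of(seg_end))})
        elif seg_kind == "intervention":
            cur, y, info = seg_payload.apply(cur, y, running_min_m)
            event_log.append({"time": seg_end, "type": "intervention", **info})
            running_min_m = min(running_min_m, y[0])

    # safety: grid must be fully filled
    assert gp == len(grid)
    r_vals = np.array([float(r_of(tt)) for tt in grid])
    s_vals = np_surprise(m_out, v_out, r_vals, params.f)
    branch_vals = np.where(s_vals > 0, 1, -1)
    return Trajectory(grid, m_out, v_out, r_vals, branch_vals, event_log, params=params)


def simulate_linearized(
    params: ModelParams,
    init: State,
    horizon: float,
    opts: SolverOptions | None = None,
) -> Trajectory:
    """Integrate the piecewise-linear system (cubic term dropped, r = 0).

    This is the system behind the half-plane stability analysis: within each
    half-plane the dynamics are exactly linear, and the branch switch of the
    learning rate is retained.
    """
    return simulate(
        params,
        constant_reality(0.0, max(horizon, 1.0)),
        init,
        horizon,
        opts,
        drop_cubic=True,
    )


def simulate_lienard(
    params: ModelParams,
    r_func: Callable[[float], float],
    dr_func: Callable[[float], float],
    init: tuple[float, float],
    horizon: float,
    opts: SolverOptions | None = None,
    t0: float = 0.0,
):
    """Integrate the second-order (Liénard) mood equation directly.

    ``init`` is ``(m(0), dm/dt(0))``.  Requires symmetric learning rates and
    differentiable reality.  Returns ``(times, m, dm_dt)`` on the output
    grid; used to cross-check the first-order system.
    """
    opts = opts or SolverOptions()

    def f_rhs(t, y):
        return [y[1], lienard_rhs(y[0], y[1], dr_func(t), params)]

    grid = _output_grid(t0, horizon, opts.output_grid_spacing)
    sol = solve_ivp(
        f_rhs,
        (t0, horizon),
        list(init),
        method=opts.method,
        rtol=opts.rel_tol,
        atol=opts.abs_tol,
        max_step=opts.max_step,
        t_eval=grid,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise DivergenceError(sol.t[-1])
    return sol.t, sol.y[0], sol.y[1]
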