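"""Quantification of mood oscillations and the bipolar limit cycle.

Above the Hopf threshold ``f*eta_m = eta_v + k`` (symmetric learning rates,
constant reality) the origin is unstable and all trajectories are confined
by the rectangle with vertices ``(+-m*, +-f*m*)`` where

    m* = sqrt((2*f*eta_m - k) / k3),

so a stable limit cycle exists (Poincare–Bendixson).  This module extracts
amplitude and period from simulated trajectories, locates the threshold by
bisection, scans amplitude against mood sensitivity (the square-root outer
bound predicts the power law), and runs the two-parameter
(f*eta_m_plus, f*eta_m_minus) stability scan whose empirical verdicts are
compared with the closed-form half-plane analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .integrator import DivergenceError, SolverOptions, Trajectory, simulate
from .linear_analysis import predict_stability
from .model_core import ModelParams, State
from .reality import constant_reality, step_protocol

__all__ = [
    "LimitCycleSummary",
    "ScanResult",
    "m_star",
    "estimate_cycle",
    "amplitude_scan",
    "stability_scan",
    "scan_agreement",
    "spiral_box_boundary_deviation",
    "hopf_threshold",
    "hopf_threshold_bisection",
    "unipolar_bias_protocol",
]


def m_star(params: ModelParams) -> float:
    """Outer-bound mood amplitude ``sqrt((2*f*eta_m - k)/k3)``.

    Positive root of the nullcline-intersection condition
    ``-f*m* = (f - k/eta_m)*m* - (k3/eta_m)*m***3``; the rectangle
    ``(+-m*, +-f*m*)`` confines all trajectories started inside it.
    Requires symmetric learning rates and ``2*f*eta_m > k``.
    """
    if not params.symmetric:
        raise ValueError("outer bound defined for symmetric learning rates only")
    arg = 2.0 * params.f_eta_m_plus - params.k
    if arg < 0:
        raise ValueError(f"no positive root: 2*f*eta_m - k = {arg:.6g} < 0")
    return math.sqrt(arg / params.k3)


def _refine_extremum(t: np.ndarray, x: np.ndarray, i: int) -> tuple[float, float]:
    """Quadratic refinement of an extremum through samples i-1, i, i+1."""
    t0, t1, t2 = t[i - 1], t[i], t[i + 1]
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    denom = (t0 - t1) * (t0 - t2) * (t1 - t2)
    if denom == 0:
        return t1, x1
    a = (t2 * (x1 - x0) + t1 * (x0 - x2) + t0 * (x2 - x1)) / denom
    b = (t2 * t2 * (x0 - x1) + t1 * t1 * (x2 - x0) + t0 * t0 * (x1 - x2)) / denom
    if a == 0:
        return t1, x1
    tv = -b / (2.0 * a)
    if not (t0 <= tv <= t2):
        return t1, x1
    c = x1 - a * t1 * t1 - b * t1
    return tv, a * tv * tv + b * tv + c


@dataclass
class LimitCycleSummary:
    """Converged oscillation metrics over the assessment window."""

    amplitude: float
    period: float
    mood_sd: float
    converged: bool
    m_star: float | None = None
    n_peaks: int = 0


def estimate_cycle(
    traj: Trajectory,
    assessment_fraction: float = 0.5,
    params: ModelParams | None = None,
) -> LimitCycleSummary:
    """Amplitude, period, and mood variability of a (possible) limit cycle.

    The first ``1 - assessment_fraction`` of the horizon is discarded as a
    transient (default: first half).  Extrema of m(t) are located from sign
    changes of the discrete derivative with quadratic refinement; amplitude
    is the mean |m| at extrema, period the mean interval between successive
    maxima, and the cycle is flagged converged when the last few maxima
    amplitudes agree to better than 1% relative spread.
    """
    if not 0 < assessment_fraction <= 1:
        raise ValueError("assessment_fraction must lie in (0, 1]")
    t0, t1 = traj.times[0], traj.times[-1]
    w = traj.window(t1 - assessment_fraction * (t1 - t0), t1)
    params = params if params is not None else traj.params
    bound = None
    if params is not None and params.symmetric and 2 * params.f_eta_m_plus > params.k:
        bound = m_star(params)

    mood_sd = float(np.std(w.m))
    dm = np.diff(w.m)
    sign = np.sign(dm)
    peak_times, peak_values, max_times = [], [], []
    for i in range(1, len(sign)):
        if sign[i] != 0 and sign[i - 1] != 0 and sign[i] != sign[i - 1]:
            tv, xv = _refine_extremum(w.times, w.m, i)
            peak_times.append(tv)
            peak_values.append(xv)
            if sign[i - 1] > 0:  # rising then falling: maximum
                max_times.append(tv)
    if not peak_times:
        return LimitCycleSummary(0.0, math.nan, mood_sd, False, bound, 0)

    amplitude = float(np.mean(np.abs(peak_values)))
    period = float(np.mean(np.diff(max_times))) if len(max_times) >= 2 else math.nan
    last = np.abs(peak_values[-6:])
    converged = False
    if len(last) >= 3 and np.mean(last) > 0:
        converged = (np.max(last) - np.min(last)) / np.mean(last) < 0.01
    return LimitCycleSummary(amplitude, period, mood_sd, converged, bound, len(peak_times))


def hopf_threshold(params: ModelParams) -> float:
    """Critical mood sensitivity ``eta_v + k`` (symmetric case)."""
    if not params.symmetric:
        raise ValueError("Hopf threshold is defined for symmetric learning rates")
    return params.eta_v + params.k


def hopf_threshold_bisection(
    params: ModelParams,
    lo_ratio: float = 0.9,
    hi_ratio: float = 1.1,
    n_iter: int = 6,
    horizon: float = 800.0,
    opts: SolverOptions | None = None,
) -> float:
    """Locate the oscillation onset empirically by bisection.

    Each candidate sensitivity is simulated from (0, -1) under r = 0 and the
    mood variability of the last third of the horizon is compared with the
    middle third.  A decaying (subthreshold) run shows a clear drop between
    the windows, while a sustained cycle — saturated or still growing —
    does not; the run is called oscillatory when the late/mid ratio exceeds
    0.9.  Returns the sensitivity at the bracketing midpoint.
    """
    opts = opts or SolverOptions(rel_tol=1e-7, abs_tol=1e-9, output_grid_spacing=0.25)
    crit = params.eta_v + params.k

    def oscillates(f_eta_m: float) -> bool:
        p = params.with_sensitivities(f_eta_m, f_eta_m)
        traj = simulate(p, constant_reality(0.0, horizon), State(0.0, -1.0), horizon, opts)
        third = (traj.times[-1] - traj.times[0]) / 3.0
        mid = traj.window(traj.times[0] + third, traj.times[0] + 2 * third)
        late = traj.window(traj.times[0] + 2 * third, traj.times[-1])
        sd_mid, sd_late = float(np.std(mid.m)), float(np.std(late.m))
        return sd_mid > 0 and sd_late > 0.9 * sd_mid

    lo, hi = lo_ratio * crit, hi_ratio * crit
    if oscillates(lo) or not oscillates(hi):
        raise RuntimeError("bisection bracket does not straddle the oscillation onset")
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if oscillates(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def amplitude_scan(
    base_params: ModelParams,
    f_eta_m_values,
    horizon: float = 150.0,
    opts: SolverOptions | None = None,
    init: State | None = None,
) -> pd.DataFrame:
    """Converged cycle amplitude vs mood sensitivity (symmetric case).

    Returns a frame with columns f_eta_m, amplitude, period, m_star,
    converged.  The outer bound predicts amplitude ~ sqrt(f_eta_m) for
    sensitivities far above threshold.
    """
    opts = opts or SolverOptions(rel_tol=1e-7, abs_tol=1e-9, output_grid_spacing=0.05)
    init = init or State(0.0, -1.0)
    rows = []
    for s in f_eta_m_values:
        p = base_params.with_sensitivities(s, s)
        if p.f_eta_m_plus <= p.eta_v + p.k:
            raise ValueError(f"f_eta_m = {s} is not supra-threshold")
        traj = simulate(p, constant_reality(0.0, horizon), init, horizon, opts)
        summ = estimate_cycle(traj, 0.5, p)
        rows.append(
            {
                "f_eta_m": s,
                "amplitude": summ.amplitude,
                "period": summ.period,
                "m_star": summ.m_star,
                "converged": summ.converged,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ScanResult:
    """Two-parameter stability scan over (f*eta_m_plus, f*eta_m_minus)."""

    plus_values: np.ndarray
    minus_values: np.ndarray
    table: pd.DataFrame  # long format, one row per grid cell
    contour_level: float

    def grid(self, column: str) -> np.ndarray:
        """Reshape a table column onto the (minus, plus) grid."""
        return (
            self.table.pivot(index="f_eta_m_minus", columns="f_eta_m_plus", values=column)
            .loc[self.minus_values, self.plus_values]
            .to_numpy()
        )


def stability_scan(
    eta_v: float,
    f: float,
    k: float,
    k3: float,
    plus_values,
    minus_values,
    horizon: float = 162.5,
    init: State | None = None,
    opts: SolverOptions | None = None,
) -> ScanResult:
    """Empirical vs analytic stability over a sensitivity grid.

    Each cell is simulated under r = 0; the empirical statistic is the
    standard deviation of mood over the second half of the horizon, and the
    stable/unstable call compares it against the contour level: the same
    statistic for the *critical* model (both sensitivities at eta_v + k)
    run under an identical protocol.  Analytic verdicts from
    :func:`~moodcycles.linear_analysis.predict_stability` are attached
    per cell; divergent cells are recorded, not fatal.
    """
    opts = opts or SolverOptions(rel_tol=1e-6, abs_tol=1e-9, output_grid_spacing=0.25)
    init = init or State(0.0, -1.0)
    crit = eta_v + k
    reality = constant_reality(0.0, horizon)

    def run_cell(sp: float, sm: float) -> float:
        p = ModelParams.from_sensitivities(sp, sm, eta_v=eta_v, f=f, k=k, k3=k3)
        traj = simulate(p, reality, init, horizon, opts)
        return estimate_cycle(traj, 0.5, p).mood_sd

    contour = run_cell(crit, crit)
    rows = []
    for sm in minus_values:
        for sp in plus_values:
            p = ModelParams.from_sensitivities(sp, sm, eta_v=eta_v, f=f, k=k, k3=k3)
            try:
                sd = run_cell(sp, sm)
                failed = False
            except DivergenceError:
                sd = math.inf
                failed = True
            report = predict_stability(p)
            rows.append(
                {
                    "f_eta_m_plus": sp,
                    "f_eta_m_minus": sm,
                    "mood_sd": sd,
                    "empirical_call": "unstable" if sd > contour else "stable",
                    "analytic_verdict": report.verdict,
                    "rule_used": report.rule_used,
                    "diverged": failed,
                }
            )
    return ScanResult(
        np.asarray(plus_values, dtype=float),
        np.asarray(minus_values, dtype=float),
        pd.DataFrame(rows),
        contour,
    )


def scan_agreement(scan: ScanResult, exclude_boundary_band: bool = True) -> float:
    """Fraction of grid cells where analytic and empirical verdicts agree.

    Cells with a degenerate analytic verdict are excluded; with
    ``exclude_boundary_band`` cells whose 4-neighbourhood contains a
    different analytic verdict (the one-cell band around the analytic
    boundary) are excluded as well.
    """
    verd = scan.grid("analytic_verdict")
    emp = scan.grid("empirical_call")
    valid = verd != "degenerate"
    if exclude_boundary_band:
        interior = valid.copy()
        ny, nx = verd.shape
        for i in range(ny):
            for j in range(nx):
                if not valid[i, j]:
                    continue
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < ny and 0 <= jj < nx and verd[ii, jj] != verd[i, j]:
                        interior[i, j] = False
        valid = interior
    if not valid.any():
        raise ValueError("no non-boundary cells in scan")
    return float(np.mean((verd == emp)[valid]))


def spiral_box_boundary_deviation(scan: ScanResult, eta_v: float, k: float) -> float:
    """Largest offset (in grid cells) of the empirical stability boundary
    from the full-cycle criterion line ``s_plus + s_minus = 2*(eta_v + k)``,
    within rows of the spiral–spiral box.

    For each row whose minus-sensitivity keeps both half-planes spirals
    across the predicted crossing, the first empirically unstable column is
    compared with the analytic crossing point.
    """
    crit = eta_v + k
    width = 2.0 * math.sqrt(eta_v * k)
    emp = scan.grid("empirical_call")
    plus, minus = scan.plus_values, scan.minus_values
    step = float(np.mean(np.diff(plus)))
    worst = 0.0
    checked = 0
    for i, sm in enumerate(minus):
        if not (crit - width < sm < crit):
            continue  # need a stable spiral on the minus side
        s_cross = 2 * crit - sm
        if not (crit < s_cross < min(crit + width, plus[-1])):
            continue  # crossing outside the spiral box or the grid
        unstable = emp[i, :] == "unstable"
        if not unstable.any():
            continue
        first = plus[np.argmax(unstable)]
        worst = max(worst, abs(first - s_cross) / step)
        checked += 1
    if checked == 0:
        raise ValueError("no scan rows cross the spiral–spiral boundary")
    return worst


def unipolar_bias_protocol(
    sensitivity_ratios: dict[str, tuple[float, float]] | None = None,
    eta_v: float = 1.85,
    f: float = 0.3,
    k: float = 1.85,
    k3: float = 0.014,
    opts: SolverOptions | None = None,
) -> dict[str, Trajectory]:
    """Canned step-reality experiment separating normal/manic/depressive bias.

    Reality drops to -4 for one week, then jumps to +4 for another week;
    subjects start at the equilibrium (0, 0).  Default sensitivity pairs
    (as multiples of eta_v + k): normal (0.4, 0.4), manic (0.8, 0.1),
    depressive (0.1, 0.8).  Asymmetric subjects over/undershoot the jumps,
    biasing time-averaged mood (manic > normal > depressive).
    """
    if sensitivity_ratios is None:
        sensitivity_ratios = {
            "normal": (0.4, 0.4),
            "manic": (0.8, 0.1),
            "depressive": (0.1, 0.8),
        }
    opts = opts or SolverOptions(rel_tol=1e-9, abs_tol=1e-11, output_grid_spacing=0.005)
    reality = step_protocol([(0.0, -4.0), (1.0, 4.0)], horizon=2.0)
    crit = eta_v + k
    out = {}
    for name, (rp, rm) in sensitivity_ratios.items():
        p = ModelParams.from_sensitivities(rp * crit, rm * crit, eta_v=eta_v, f=f, k=k, k3=k3)
        out[name] = simulate(p, reality, State(0.0, 0.0), 2.0, opts)
    return out
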