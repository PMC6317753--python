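"""Reality processes r(t) as piecewise-constant functions with known jumps.

Reality models the stream of external life events.  Two deterministic forms
(constant level, explicit step protocol) and one stochastic form are
provided.  The stochastic process is a renewal process: segment levels are
i.i.d. Normal(0, sigma_r**2) and segment durations are i.i.d. lognormal
whose *underlying log-duration* has mean 1/k_r and standard deviation 1/k_r
(both in weeks).  Realizations are generated with numpy's seeded PCG64
generator (``numpy.random.default_rng``), so a seed pins the realization
bit-for-bit across machines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RealityRealization",
    "StochasticRealityConfig",
    "constant_reality",
    "step_protocol",
    "random_reality",
    "draw_segments",
]


@dataclass(frozen=True)
class RealityRealization:
    """A piecewise-constant reality function on [0, horizon].

    ``r(t) = levels[i]`` for ``t in [jump_times[i], jump_times[i+1])``
    (right-open intervals: a query exactly at a jump returns the new level).
    Queries before the first jump return ``levels[0]``; queries at or past
    the horizon return the last level.
    """

    jump_times: np.ndarray
    levels: np.ndarray
    horizon: float

    def __post_init__(self) -> None:
        jt = np.asarray(self.jump_times, dtype=float)
        lv = np.asarray(self.levels, dtype=float)
        object.__setattr__(self, "jump_times", jt)
        object.__setattr__(self, "levels", lv)
        if jt.ndim != 1 or lv.ndim != 1 or len(jt) != len(lv):
            raise ValueError("jump_times and levels must be 1-D and equal length")
        if len(jt) == 0:
            raise ValueError("need at least one segment")
        if jt[0] != 0.0:
            raise ValueError("first jump time must be 0")
        if np.any(np.diff(jt) <= 0):
            raise ValueError("jump times must be strictly increasing")
        if not self.horizon > 0:
            raise ValueError("horizon must be positive")

    def __call__(self, t):
        """Evaluate r(t); scalar or array argument."""
        idx = np.searchsorted(self.jump_times, t, side="right") - 1
        idx = np.clip(idx, 0, len(self.levels) - 1)
        out = self.levels[idx]
        if np.isscalar(t):
            return float(out)
        return out

    def jumps_within(self, t0: float, t1: float) -> np.ndarray:
        """Jump times strictly inside (t0, t1)."""
        jt = self.jump_times
        return jt[(jt > t0) & (jt < t1)]

    @property
    def durations(self) -> np.ndarray:
        """Segment durations; the last segment is truncated at the horizon."""
        edges = np.append(self.jump_times, self.horizon)
        return np.diff(edges)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"jump_time": self.jump_times, "level": self.levels})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, horizon: float) -> "RealityRealization":
        return cls(df["jump_time"].to_numpy(), df["level"].to_numpy(), horizon)


@dataclass(frozen=True)
class StochasticRealityConfig:
    """Parameters of the random reality renewal process.

    sigma_r : standard deviation of the Normal(0, sigma_r^2) levels.
    k_r     : inverse mean (and inverse s.d.) of the log segment duration
              (1/weeks); larger k_r means shorter, more regular segments.
    seed    : RNG seed; identical seeds give bit-identical realizations.
    horizon : end time of the realization (weeks).
    """

    sigma_r: float
    k_r: float
    seed: int
    horizon: float = 162.5

    def __post_init__(self) -> None:
        if self.sigma_r < 0:
            raise ValueError("sigma_r must be >= 0")
        if not self.k_r > 0:
            raise ValueError("k_r must be > 0")
        if not self.horizon > 0:
            raise ValueError("horizon must be > 0")


def constant_reality(r0: float, horizon: float) -> RealityRealization:
    """Constant reality r(t) = r0 on [0, horizon]."""
    return RealityRealization(np.array([0.0]), np.array([float(r0)]), horizon)


def step_protocol(breaks, horizon: float) -> RealityRealization:
    """Piecewise-constant reality from explicit (time, level) breakpoints.

    ``breaks`` must be sorted, start at t = 0, and contain no duplicate
    times.  Example: ``step_protocol([(0, -4), (1, 4)], horizon=2)`` drops
    reality to -4 for the first week and raises it to +4 afterwards.
    """
    times = np.array([b[0] for b in breaks], dtype=float)
    levels = np.array([b[1] for b in breaks], dtype=float)
    if len(times) == 0 or times[0] != 0.0:
        raise ValueError("breaks must start at time 0")
    if np.any(np.diff(times) <= 0):
        raise ValueError("break times must be strictly increasing (no duplicates)")
    return RealityRealization(times, levels, horizon)


def draw_segments(config: StochasticRealityConfig, n: int, rng=None):
    """Draw ``n`` (level, duration) pairs of the renewal process.

    Levels ~ Normal(0, sigma_r^2); durations = exp(Normal(1/k_r, (1/k_r)^2)).
    Exposed separately so distributional tests can reach the raw draws.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    levels = rng.normal(0.0, config.sigma_r, size=n)
    log_durations = rng.normal(1.0 / config.k_r, 1.0 / config.k_r, size=n)
    return levels, np.exp(log_durations)


def random_reality(config: StochasticRealityConfig) -> RealityRealization:
    """Seeded random reality realization truncated at the horizon.

    Segments are generated past the horizon and then truncated, so the
    realization covers [0, horizon] entirely; the first segment starts at
    t = 0 with a drawn level, and levels carry no autocorrelation.
    """
    rng = np.random.default_rng(config.seed)
    jump_times = [0.0]
    levels: list[float] = []
    t = 0.0
    while t <= config.horizon:
        chunk_levels, chunk_durations = draw_segments(config, 64, rng)
        for lv, dur in zip(chunk_levels, chunk_durations):
            levels.append(float(lv))
            t += float(dur)
            jump_times.append(t)
            if t > config.horizon:
                break
    jt = np.array(jump_times[: len(levels)])
    lv = np.array(levels)
    keep = jt < config.horizon
    return RealityRealization(jt[keep], lv[keep], config.horizon)
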