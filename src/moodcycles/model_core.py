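"""Core mood–expectation dynamics.

The model couples a dimensionless mood ``m(t)`` to a learned expectation
``v(t)`` through the *perceived surprise* ``f*m + r - v``: external reality
``r(t)`` is additively biased by the current mood (scale ``f``), and the
mismatch with expectation drives both variables,

    dm/dt = eta_m * (f*m + r - v) - k*m - k3*m**3
    dv/dt = eta_v * (f*m + r - v)

Mood relaxes to baseline through a linear (``k``) and a saturating cubic
(``k3``) recovery force; the expectation simply tracks perceived reality at
rate ``eta_v``.  The mood learning rate may differ for positive and negative
surprises (``eta_m_plus`` / ``eta_m_minus``), which makes the vector field
continuous but non-smooth across the switching line ``f*m + r - v = 0``.

Time is measured in weeks throughout the package; all rates are per week.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ModelParams",
    "State",
    "surprise",
    "select_eta_m",
    "rhs",
    "lienard_rhs",
]


@dataclass(frozen=True)
class ModelParams:
    """Rate constants and sensitivities of the mood–expectation model.

    Parameters
    ----------
    eta_m_plus, eta_m_minus : float
        Mood learning rates for positive / non-positive surprise (1/week).
    eta_v : float
        Expectation learning rate (1/week).
    f : float
        Dimensionless scale of the mood contribution to perceived reality.
    k : float
        Linear mood recovery rate (1/week).
    k3 : float
        Cubic mood recovery coefficient (1/(mood^2 * week)).

    The bifurcation parameter of the model is the *mood sensitivity*
    ``f * eta_m``; the fixed point at the origin loses stability when it
    exceeds ``eta_v + k``.
    """

    eta_m_plus: float
    eta_m_minus: float
    eta_v: float
    f: float
    k: float
    k3: float

    def __post_init__(self) -> None:
        for name in ("eta_m_plus", "eta_m_minus", "eta_v", "f", "k", "k3"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be a strictly positive finite number, got {value!r}")

    @property
    def symmetric(self) -> bool:
        """True iff positive and negative mood learning rates coincide."""
        return self.eta_m_plus == self.eta_m_minus

    @property
    def f_eta_m_plus(self) -> float:
        """Positive-branch mood sensitivity ``f * eta_m_plus``."""
        return self.f * self.eta_m_plus

    @property
    def f_eta_m_minus(self) -> float:
        """Negative-branch mood sensitivity ``f * eta_m_minus``."""
        return self.f * self.eta_m_minus

    @property
    def critical_sensitivity(self) -> float:
        """Hopf threshold ``eta_v + k`` of the mood sensitivity."""
        return self.eta_v + self.k

    @classmethod
    def from_sensitivities(
        cls,
        f_eta_m_plus: float,
        f_eta_m_minus: float | None = None,
        *,
        eta_v: float,
        f: float,
        k: float,
        k3: float,
    ) -> "ModelParams":
        """Build parameters from mood sensitivities ``f*eta_m`` directly."""
        if f_eta_m_minus is None:
            f_eta_m_minus = f_eta_m_plus
        return cls(
            eta_m_plus=f_eta_m_plus / f,
            eta_m_minus=f_eta_m_minus / f,
            eta_v=eta_v,
            f=f,
            k=k,
            k3=k3,
        )

    @classmethod
    def from_ratios(
        cls,
        ratio_plus: float,
        ratio_minus: float | None = None,
        *,
        eta_v: float = 0.37,
        f: float = 0.3,
        k: float = 0.37,
        k3: float = 2.8e-3,
    ) -> "ModelParams":
        """Build parameters from sensitivities given as multiples of the
        Hopf threshold ``eta_v + k``.

        Defaults are the canonical per-week parameter set used throughout the
        package's worked examples (``eta_v = k = 0.37``, ``f = 0.3``,
        ``k3 = 2.8e-3``); ``ratio = 1`` sits exactly at the bifurcation.
        """
        crit = eta_v + k
        if ratio_minus is None:
            ratio_minus = ratio_plus
        return cls.from_sensitivities(
            ratio_plus * crit, ratio_minus * crit, eta_v=eta_v, f=f, k=k, k3=k3
        )

    def with_sensitivities(
        self, f_eta_m_plus: float | None = None, f_eta_m_minus: float | None = None
    ) -> "ModelParams":
        """Copy with one or both mood sensitivities replaced."""
        kwargs = {}
        if f_eta_m_plus is not None:
            kwargs["eta_m_plus"] = f_eta_m_plus / self.f
        if f_eta_m_minus is not None:
            kwargs["eta_m_minus"] = f_eta_m_minus / self.f
        return replace(self, **kwargs)

    def scaled_sensitivities(self, factor: float) -> "ModelParams":
        """Copy with both mood learning rates multiplied by ``factor``."""
        return replace(
            self,
            eta_m_plus=self.eta_m_plus * factor,
            eta_m_minus=self.eta_m_minus * factor,
        )


@dataclass(frozen=True)
class State:
    """Instantaneous state: mood ``m``, expectation ``v``, time ``t`` (weeks)."""

    m: float
    v: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if not all(math.isfinite(x) for x in (self.m, self.v, self.t)):
            raise ValueError(f"state must be finite, got {self}")


def _logistic(x: float) -> float:
    """Overflow-safe standard logistic."""
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    ex = math.exp(x)
    return ex / (1.0 + ex)


def surprise(m: float, v: float, r: float, f: float) -> float:
    """Perceived surprise (prediction error) ``f*m + r - v``.

    Its sign selects the active mood learning rate: positive surprises use
    ``eta_m_plus``, non-positive surprises (boundary included) use
    ``eta_m_minus``.
    """
    return f * m + r - v


def select_eta_m(m: float, v: float, r: float, params: ModelParams) -> float:
    """Active mood learning rate for the current surprise sign.

    The switching boundary ``f*m + r - v = 0`` is assigned to the minus
    branch.
    """
    if surprise(m, v, r, params.f) > 0:
        return params.eta_m_plus
    return params.eta_m_minus


def rhs(
    m: float,
    v: float,
    r: float,
    params: ModelParams,
    *,
    drop_cubic: bool = False,
    smoothing: float = 0.0,
) -> tuple[float, float]:
    """Right-hand side ``(dm/dt, dv/dt)`` of the mood–expectation system.

    Parameters
    ----------
    drop_cubic : bool
        Drop the ``-k3*m**3`` term (the piecewise-linear system used in the
        half-plane stability analysis).
    smoothing : float
        If positive, blend the two learning rates through a logistic of the
        surprise with this width instead of a hard switch.  Off by default;
        intended for robustness experiments only.
    """
    if not (math.isfinite(m) and math.isfinite(v) and math.isfinite(r)):
        raise FloatingPointError(f"non-finite state in rhs: m={m}, v={v}, r={r}")
    s = surprise(m, v, r, params.f)
    if smoothing > 0.0:
        w = _logistic(s / smoothing)
        eta_m = params.eta_m_minus + (params.eta_m_plus - params.eta_m_minus) * w
    else:
        eta_m = params.eta_m_plus if s > 0 else params.eta_m_minus
    dm = eta_m * s - params.k * m
    if not drop_cubic:
        dm -= params.k3 * m**3
    dv = params.eta_v * s
    return dm, dv


def lienard_rhs(m: float, dm_dt: float, dr_dt: float, params: ModelParams) -> float:
    """Mood acceleration of the equivalent second-order (Liénard) form.

    Eliminating the expectation turns the system into a single nonlinear
    oscillator in mood,

        m'' = (f*eta_m - k - eta_v - 3*k3*m**2) m' - eta_v*k*m - eta_v*k3*m**3
              + eta_m * dr/dt,

    a van der Pol–like equation forced by *changes* in reality.  The form is
    only defined for symmetric learning rates (a single ``eta_m``) and a
    differentiable reality.
    """
    if not params.symmetric:
        raise ValueError("Lienard form is undefined for asymmetric mood learning rates")
    eta_m = params.eta_m_plus
    damping = params.f * eta_m - params.k - params.eta_v - 3.0 * params.k3 * m**2
    return (
        damping * dm_dt
        - params.eta_v * params.k * m
        - params.eta_v * params.k3 * m**3
        + eta_m * dr_dt
    )


def np_surprise(m: np.ndarray, v: np.ndarray, r: np.ndarray, f: float) -> np.ndarray:
    """Vectorized perceived surprise for trajectory post-processing."""
    return f * np.asarray(m) + np.asarray(r) - np.asarray(v)
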