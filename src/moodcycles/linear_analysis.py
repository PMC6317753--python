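"""Closed-form stability analysis of the origin.

Linearizing the system about (m, v) = (0, 0) for r = 0 (dropping the cubic
term) gives the Jacobian

    J = [[f*eta_m - k,  -eta_m],
         [f*eta_v,      -eta_v]]

with trace ``f*eta_m - eta_v - k``, determinant ``eta_v*k``, eigenvalues

    lambda_pm = (f*eta_m - eta_v - k)/2 +- sqrt(D)/2,
    D = (f*eta_m - eta_v - k)**2 - 4*eta_v*k.

With asymmetric learning rates the phase plane splits into two half-planes
across ``v = f*m``, each governed by its own linear system.  Each half-plane
is a node or a spiral, stable or unstable; when both are spirals the overall
stability follows from concatenating half-cycle arcs: over one half-cycle in
a spiral half-plane the distance to the origin is multiplied by

    exp( pi * tr / sqrt(4*eta_v*k - tr**2) ),   tr = f*eta_m - eta_v - k,

and the origin is stable over a full cycle iff the sum of the two exponents
is negative.  When a node coexists with a spiral the node's stability wins
(most node-half-plane trajectories never leave it); the stable-node /
unstable-node coexistence case is reported unstable, flagged as
initial-condition-sensitive because numerical outcomes depend on where the
trajectory starts.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass

import numpy as np

from .model_core import ModelParams

__all__ = [
    "Branch",
    "Regime",
    "EigenReport",
    "HalfPlaneLinearSolution",
    "StabilityReport",
    "jacobian",
    "eigenvalues",
    "classify_halfplane",
    "half_plane_solution",
    "half_cycle_multiplier",
    "eq11_value",
    "predict_stability",
    "DegenerateParameters",
]

_BOUNDARY_RTOL = 1e-9


class DegenerateParameters(ValueError):
    """Parameters sit exactly on a regime boundary; classification undefined."""


class Branch(str, enum.Enum):
    PLUS = "plus"
    MINUS = "minus"


class Regime(str, enum.Enum):
    STABLE_NODE = "stable_node"
    STABLE_SPIRAL = "stable_spiral"
    UNSTABLE_SPIRAL = "unstable_spiral"
    UNSTABLE_NODE = "unstable_node"

    @property
    def is_stable(self) -> bool:
        return self in (Regime.STABLE_NODE, Regime.STABLE_SPIRAL)

    @property
    def is_spiral(self) -> bool:
        return self in (Regime.STABLE_SPIRAL, Regime.UNSTABLE_SPIRAL)


def _f_eta_m(params: ModelParams, branch: Branch) -> float:
    return params.f_eta_m_plus if branch == Branch.PLUS else params.f_eta_m_minus


def jacobian(params: ModelParams, branch: Branch) -> np.ndarray:
    """Jacobian of the linearized dynamics for one learning-rate branch."""
    eta_m = params.eta_m_plus if branch == Branch.PLUS else params.eta_m_minus
    return np.array(
        [
            [params.f * eta_m - params.k, -eta_m],
            [params.f * params.eta_v, -params.eta_v],
        ]
    )


@dataclass(frozen=True)
class EigenReport:
    """Eigenvalues of one half-plane's linear dynamics (1/week)."""

    lambda_plus: complex
    lambda_minus: complex
    discriminant: float
    trace: float
    branch: Branch


def eigenvalues(params: ModelParams, branch: Branch = Branch.PLUS) -> EigenReport:
    """Closed-form eigenvalues ``(tr +- sqrt(D))/2`` for one branch."""
    tr = _f_eta_m(params, branch) - params.eta_v - params.k
    disc = tr * tr - 4.0 * params.eta_v * params.k
    root = complex(math.sqrt(disc)) if disc >= 0 else complex(0.0, math.sqrt(-disc))
    return EigenReport(
        lambda_plus=(tr + root) / 2.0,
        lambda_minus=(tr - root) / 2.0,
        discriminant=disc,
        trace=tr,
        branch=branch,
    )


def classify_halfplane(params: ModelParams, branch: Branch) -> Regime:
    """Node/spiral, stable/unstable classification of one half-plane.

    Boundaries (trace zero or discriminant zero) are excluded: parameters
    within relative tolerance 1e-9 of a boundary raise
    :class:`DegenerateParameters` rather than being silently classified.
    """
    s = _f_eta_m(params, branch)
    crit = params.eta_v + params.k
    width = 2.0 * math.sqrt(params.eta_v * params.k)
    scale = max(abs(crit), abs(width), 1e-300)
    for boundary in (crit - width, crit, crit + width):
        if abs(s - boundary) <= _BOUNDARY_RTOL * scale:
            raise DegenerateParameters(
                f"mood sensitivity {s:.12g} on the {branch.value}-branch sits on a "
                f"regime boundary (boundaries at {crit - width:.12g}, {crit:.12g}, "
                f"{crit + width:.12g})"
            )
    if s < crit - width:
        return Regime.STABLE_NODE
    if s < crit:
        return Regime.STABLE_SPIRAL
    if s < crit + width:
        return Regime.UNSTABLE_SPIRAL
    return Regime.UNSTABLE_NODE


@dataclass(frozen=True)
class HalfPlaneLinearSolution:
    """Explicit spiral solution of one half-plane's linear system.

    m(t) = exp(gr*t) (A cos(w t) + B sin(w t)),
    v(t) = exp(gr*t) (C cos(w t) + D sin(w t)),

    with growth rate gr = tr/2 and angular frequency
    w = sqrt(4*eta_v*k - tr**2)/2.  The coefficients follow from the initial
    condition; they do not enter the stability criterion.  The half-cycle
    time (boundary to boundary) is pi/w.
    """

    growth_rate: float
    angular_frequency: float
    A: float
    B: float
    C: float
    D: float

    @property
    def half_cycle_time(self) -> float:
        return math.pi / self.angular_frequency

    def evaluate(self, t):
        t = np.asarray(t, dtype=float)
        e = np.exp(self.growth_rate * t)
        c, s = np.cos(self.angular_frequency * t), np.sin(self.angular_frequency * t)
        return e * (self.A * c + self.B * s), e * (self.C * c + self.D * s)


def half_plane_solution(
    params: ModelParams, branch: Branch, m0: float, v0: float
) -> HalfPlaneLinearSolution:
    """Spiral-branch closed-form solution through (m0, v0) at t = 0."""
    regime = classify_halfplane(params, branch)
    if not regime.is_spiral:
        raise ValueError(f"{branch.value}-branch is a {regime.value}, not a spiral")
    rep = eigenvalues(params, branch)
    gr = rep.trace / 2.0
    w = math.sqrt(-rep.discriminant) / 2.0
    J = jacobian(params, branch)
    dm0 = J[0, 0] * m0 + J[0, 1] * v0
    dv0 = J[1, 0] * m0 + J[1, 1] * v0
    return HalfPlaneLinearSolution(
        growth_rate=gr,
        angular_frequency=w,
        A=m0,
        B=(dm0 - gr * m0) / w,
        C=v0,
        D=(dv0 - gr * v0) / w,
    )


def half_cycle_multiplier(params: ModelParams, branch: Branch) -> float:
    """Distance-to-origin factor over one half-cycle in a spiral half-plane.

    exp( pi*tr / sqrt(4*eta_v*k - tr**2) ); > 1 grows, < 1 contracts.
    """
    regime = classify_halfplane(params, branch)
    if not regime.is_spiral:
        raise ValueError(
            f"half-cycle multiplier requires a spiral half-plane; "
            f"{branch.value}-branch is a {regime.value}"
        )
    tr = _f_eta_m(params, branch) - params.eta_v - params.k
    return math.exp(math.pi * tr / math.sqrt(4.0 * params.eta_v * params.k - tr * tr))


def eq11_value(params: ModelParams) -> float:
    """Full-cycle log growth: sum of the two half-cycle exponents.

    Defined only when both half-planes are spirals; negative means the
    trajectory moves closer to the origin after a full cycle (stability).
    """
    total = 0.0
    for branch in (Branch.PLUS, Branch.MINUS):
        regime = classify_halfplane(params, branch)
        if not regime.is_spiral:
            raise ValueError(
                f"full-cycle criterion requires spirals in both half-planes; "
                f"{branch.value}-branch is a {regime.value}"
            )
        tr = _f_eta_m(params, branch) - params.eta_v - params.k
        total += math.pi * tr / math.sqrt(4.0 * params.eta_v * params.k - tr * tr)
    return total


@dataclass(frozen=True)
class StabilityReport:
    """Overall linear-stability verdict for the origin."""

    regime_plus: Regime | None
    regime_minus: Regime | None
    eq11: float | None
    verdict: str  # stable | unstable | degenerate
    rule_used: str
    initial_condition_sensitive: bool = False

    def to_dict(self) -> dict:
        d = {
            "regime_plus": None if self.regime_plus is None else self.regime_plus.value,
            "regime_minus": None if self.regime_minus is None else self.regime_minus.value,
            "eq11_value": self.eq11,
            "verdict": self.verdict,
            "rule_used": self.rule_used,
            "initial_condition_sensitive": self.initial_condition_sensitive,
        }
        return d

    def to_json(self, params: ModelParams | None = None) -> str:
        d = self.to_dict()
        if params is not None:
            for branch in (Branch.PLUS, Branch.MINUS):
                rep = eigenvalues(params, branch)
                d[f"eigenvalues_{branch.value}"] = {
                    "lambda_plus": [rep.lambda_plus.real, rep.lambda_plus.imag],
                    "lambda_minus": [rep.lambda_minus.real, rep.lambda_minus.imag],
                    "discriminant": rep.discriminant,
                    "trace": rep.trace,
                }
        return json.dumps(d, indent=2)


def predict_stability(params: ModelParams) -> StabilityReport:
    """Overall verdict from the per-half-plane regimes.

    Decision table: both stable -> stable; both unstable -> unstable;
    node + spiral -> the node's stability; stable spiral + unstable spiral
    -> sign of the full-cycle criterion; stable node + unstable node ->
    unstable (numerical observation), flagged initial-condition-sensitive.
    Boundary parameters give a 'degenerate' verdict.
    """
    try:
        rp = classify_halfplane(params, Branch.PLUS)
        rm = classify_halfplane(params, Branch.MINUS)
    except DegenerateParameters as exc:
        return StabilityReport(None, None, None, "degenerate", f"boundary: {exc}")

    eq11 = None
    if rp.is_spiral and rm.is_spiral:
        eq11 = eq11_value(params)

    if rp.is_stable and rm.is_stable:
        return StabilityReport(rp, rm, eq11, "stable", "both_halfplanes_stable")
    if not rp.is_stable and not rm.is_stable:
        return StabilityReport(rp, rm, eq11, "unstable", "both_halfplanes_unstable")
    # mixed stability
    if rp.is_spiral and rm.is_spiral:
        verdict = "stable" if eq11 < 0 else "unstable"
        return StabilityReport(rp, rm, eq11, verdict, "spiral_spiral_full_cycle")
    if {rp, rm} == {Regime.STABLE_NODE, Regime.UNSTABLE_NODE}:
        return StabilityReport(
            rp,
            rm,
            eq11,
            "unstable",
            "node_node_numerical_observation",
            initial_condition_sensitive=True,
        )
    # one node, one spiral, opposite stability: the node decides
    node = rp if not rp.is_spiral else rm
    verdict = "stable" if node.is_stable else "unstable"
    return StabilityReport(rp, rm, eq11, verdict, "node_dominates_spiral")
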