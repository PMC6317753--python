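"""Closed-form stability machinery vs numerical oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moodcycles import ModelParams, SolverOptions, State, simulate_linearized
from moodcycles.linear_analysis import (
    Branch,
    DegenerateParameters,
    Regime,
    classify_halfplane,
    eigenvalues,
    eq11_value,
    half_cycle_multiplier,
    half_plane_solution,
    jacobian,
    predict_stability,
)

RATE = st.floats(min_value=0.05, max_value=5.0)


def params_from(f_eta_m_plus, f_eta_m_minus=None, eta_v=0.37, k=0.37, f=0.3, k3=2.8e-3):
    return ModelParams.from_sensitivities(
        f_eta_m_plus, f_eta_m_minus, eta_v=eta_v, f=f, k=k, k3=k3
    )


class TestEigenvalues:
    def test_purely_imaginary_at_threshold(self):
        rep = eigenvalues(params_from(0.74))
        assert rep.trace == pytest.approx(0.0, abs=1e-15)
        assert rep.discriminant == pytest.approx(-4 * 0.37 * 0.37)
        assert rep.lambda_plus == pytest.approx(0.37j)
        assert rep.lambda_minus == pytest.approx(-0.37j)

    def test_subthreshold_spiral_values(self):
        rep = eigenvalues(params_from(0.222))
        assert rep.lambda_plus.real == pytest.approx(-0.259)
        assert rep.lambda_plus.imag == pytest.approx(0.2642, abs=5e-4)

    def test_real_eigenvalues_when_k_vanishes(self):
        # k -> 0 limit: discriminant (f*eta_m - eta_v)^2 >= 0, both real
        for s in (0.1, 0.37, 2.0):
            rep = eigenvalues(params_from(s, k=1e-12))
            assert abs(rep.lambda_plus.imag) < 1e-6
            assert abs(rep.lambda_minus.imag) < 1e-6

    @given(s=RATE, eta_v=RATE, k=RATE)
    @settings(max_examples=200, deadline=None)
    def test_trace_determinant_identities(self, s, eta_v, k):
        rep = eigenvalues(params_from(s, eta_v=eta_v, k=k))
        lam_sum = rep.lambda_plus + rep.lambda_minus
        lam_prod = rep.lambda_plus * rep.lambda_minus
        assert lam_sum.real == pytest.approx(s - eta_v - k, rel=1e-12, abs=1e-12)
        assert abs(lam_sum.imag) < 1e-12
        assert lam_prod.real == pytest.approx(eta_v * k, rel=1e-12, abs=1e-12)

    def test_agrees_with_numerical_eigendecomposition(self, rng):
        for _ in range(200):
            s, eta_v, k = rng.uniform(0.05, 5.0, 3)
            p = params_from(s, eta_v=eta_v, k=k)
            rep = eigenvalues(p)
            numeric = np.linalg.eigvals(jacobian(p, Branch.PLUS))
            closed = sorted([rep.lambda_plus, rep.lambda_minus], key=lambda z: (z.real, z.imag))
            numeric = sorted(numeric, key=lambda z: (z.real, z.imag))
            assert np.allclose(closed, numeric, atol=1e-10)


class TestClassification:
    # eta_v = 1.48, k = 0.37: boundaries at 0.37, 1.85, 3.33
    @pytest.mark.parametrize(
        "s, regime",
        [
            (0.2, Regime.STABLE_NODE),
            (1.0, Regime.STABLE_SPIRAL),
            (2.22, Regime.UNSTABLE_SPIRAL),
            (4.0, Regime.UNSTABLE_NODE),
        ],
    )
    def test_regimes(self, s, regime):
        p = params_from(s, eta_v=1.48, k=0.37)
        assert classify_halfplane(p, Branch.PLUS) is regime

    def test_boundary_raises_degenerate(self):
        with pytest.raises(DegenerateParameters):
            classify_halfplane(params_from(0.74), Branch.PLUS)  # trace = 0 exactly

    def test_classification_consistent_with_eigenvalues(self, rng):
        for _ in range(100):
            s, eta_v, k = rng.uniform(0.05, 5.0, 3)
            p = params_from(s, eta_v=eta_v, k=k)
            try:
                regime = classify_halfplane(p, Branch.PLUS)
            except DegenerateParameters:
                continue
            rep = eigenvalues(p)
            assert regime.is_stable == (rep.lambda_plus.real < 0 and rep.lambda_minus.real < 0)
            assert regime.is_spiral == (rep.discriminant < 0)


class TestHalfCycleMultiplier:
    def test_unity_at_threshold_limit(self):
        # trace -> 0: multiplier -> 1; evaluate just off the boundary
        p = params_from(0.74 + 1e-6)
        assert half_cycle_multiplier(p, Branch.PLUS) == pytest.approx(1.0, abs=1e-5)

    def test_printed_spiral_example(self):
        p = params_from(2.22, eta_v=1.48, k=0.37)
        assert half_cycle_multiplier(p, Branch.PLUS) == pytest.approx(2.2505, abs=2e-4)

    @given(x=st.floats(min_value=0.01, max_value=1.3))
    @settings(max_examples=50, deadline=None)
    def test_reciprocal_symmetry_about_threshold(self, x):
        eta_v, k = 1.48, 0.37
        crit = eta_v + k
        up = half_cycle_multiplier(params_from(crit + x, eta_v=eta_v, k=k), Branch.PLUS)
        down = half_cycle_multiplier(params_from(crit - x, eta_v=eta_v, k=k), Branch.PLUS)
        assert up * down == pytest.approx(1.0, rel=1e-12)

    def test_node_branch_rejected(self):
        with pytest.raises(ValueError, match="spiral"):
            half_cycle_multiplier(params_from(0.2, eta_v=1.48, k=0.37), Branch.PLUS)

    def test_matches_simulated_distance_ratio(self):
        """Closed form vs a tight-tolerance integration over one half-cycle."""
        p = params_from(2.22, 1.48, eta_v=1.48, k=0.37)
        rep = eigenvalues(p, Branch.PLUS)
        dt = 2 * math.pi / math.sqrt(-rep.discriminant)
        opts = SolverOptions(rel_tol=1e-12, abs_tol=1e-14, output_grid_spacing=dt / 100, method="DOP853")
        m0 = 1.0
        traj = simulate_linearized(p, State(-m0, -p.f * m0), dt, opts)  # plus half-plane
        ratio = math.hypot(traj.m[-1], traj.v[-1]) / math.hypot(m0, p.f * m0)
        assert ratio == pytest.approx(half_cycle_multiplier(p, Branch.PLUS), rel=1e-8)


class TestHalfPlaneSolution:
    def test_solution_satisfies_linear_ode(self):
        p = params_from(2.22, eta_v=1.48, k=0.37)
        sol = half_plane_solution(p, Branch.PLUS, m0=0.7, v0=-0.2)
        J = jacobian(p, Branch.PLUS)
        h = 1e-6
        for t in (0.0, 0.4, 1.7):
            m, v = sol.evaluate(t)
            mp, vp = sol.evaluate(t + h)
            mm, vm = sol.evaluate(t - h)
            dm, dv = (mp - mm) / (2 * h), (vp - vm) / (2 * h)
            assert dm == pytest.approx(J[0, 0] * m + J[0, 1] * v, rel=1e-5, abs=1e-8)
            assert dv == pytest.approx(J[1, 0] * m + J[1, 1] * v, rel=1e-5, abs=1e-8)

    def test_initial_condition_recovered(self):
        p = params_from(1.0, eta_v=1.48, k=0.37)
        sol = half_plane_solution(p, Branch.PLUS, m0=0.7, v0=-0.2)
        m, v = sol.evaluate(0.0)
        assert (m, v) == pytest.approx((0.7, -0.2))


class TestEq11:
    def test_zero_on_the_balance_line(self):
        # f*(eta_m_plus + eta_m_minus) = 2*(eta_v + k) gives exact balance
        p = params_from(2.22, 1.48, eta_v=1.48, k=0.37)
        assert eq11_value(p) == pytest.approx(0.0, abs=1e-12)

    def test_negative_for_symmetric_subthreshold_spirals(self):
        assert eq11_value(params_from(0.5)) < 0

    def test_log_product_identity(self, rng):
        for _ in range(50):
            eta_v, k = rng.uniform(0.2, 3.0, 2)
            crit, width = eta_v + k, 2 * math.sqrt(eta_v * k)
            sp = crit + rng.uniform(0.05, 0.95) * width
            sm = crit - rng.uniform(0.05, 0.95) * width
            p = params_from(sp, sm, eta_v=eta_v, k=k)
            logprod = math.log(
                half_cycle_multiplier(p, Branch.PLUS) * half_cycle_multiplier(p, Branch.MINUS)
            )
            assert eq11_value(p) == pytest.approx(logprod, abs=1e-10)

    def test_requires_spirals(self):
        with pytest.raises(ValueError, match="spiral"):
            eq11_value(params_from(0.2, 1.0, eta_v=1.48, k=0.37))


class TestPredictStability:
    def test_both_subthreshold_stable(self):
        rep = predict_stability(params_from(0.4 * 0.74, 0.4 * 0.74))
        assert rep.verdict == "stable"

    def test_both_suprathreshold_unstable(self):
        # note: with eta_v = k, ratio 2 sits exactly on the spiral/node
        # boundary, so probe on both sides of it
        for ratio in (1.5, 2.2):
            rep = predict_stability(params_from(ratio * 0.74, ratio * 0.74))
            assert rep.verdict == "unstable"

    def test_unstable_spiral_with_stable_node_is_stable(self):
        # the node's half-plane dominates
        rep = predict_stability(params_from(2.22, 0.2, eta_v=1.48, k=0.37))
        assert rep.verdict == "stable"
        assert rep.rule_used == "node_dominates_spiral"

    def test_spiral_spiral_follows_full_cycle_sign(self):
        below = predict_stability(params_from(2.0, 1.5, eta_v=1.48, k=0.37))  # sum < 2*crit
        above = predict_stability(params_from(2.4, 1.5, eta_v=1.48, k=0.37))  # sum > 2*crit
        assert below.verdict == "stable" and below.eq11 < 0
        assert above.verdict == "unstable" and above.eq11 > 0

    def test_node_node_coexistence_flagged(self):
        rep = predict_stability(params_from(4.0, 0.2, eta_v=1.48, k=0.37))
        assert rep.verdict == "unstable"
        assert rep.initial_condition_sensitive

    def test_boundary_gives_degenerate_verdict(self):
        rep = predict_stability(params_from(0.74, 0.5 * 0.74))
        assert rep.verdict == "degenerate"


def test_damped_oscillation_frequency_matches_imaginary_part(canonical_params):
    """Measured ringing frequency of a subthreshold run equals sqrt(-D)/2 within 2%."""
    from moodcycles import constant_reality, simulate

    p = canonical_params
    rep = eigenvalues(p)
    opts = SolverOptions(rel_tol=1e-10, abs_tol=1e-12, output_grid_spacing=0.02)
    traj = simulate(p, constant_reality(0.0, 80.0), State(0.0, -1.0), 80.0, opts)
    s = np.sign(traj.m)
    crossings = traj.times[1:][np.diff(s) != 0]
    omega = math.pi / np.mean(np.diff(crossings))
    assert omega == pytest.approx(math.sqrt(-rep.discriminant) / 2, rel=0.02)
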