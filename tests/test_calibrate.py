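"""Minimum chi-square calibration: closed forms, nonlinear solvers,
reduction identities and domain estimates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from domcal import (
    calibrate_stratum,
    domain_estimate,
    estimate_all,
    linear_calibrated_weights,
    q_weights,
    solve_exponential_multiplier,
    solve_linear_multiplier,
    solve_power_parameter,
    summarize_domains,
)
from domcal.calibrate import CalibrationError
from domcal.design import draw_realization, hansen_hurwitz_total


def ratio_estimator_direct(d1, y1, x1, d2, y2, x2, X1a, X2a):
    """Independent coding of the ratio form: (sum dy / sum dx) * target
    per stratum."""
    value = np.sum(d1 * y1) / np.sum(d1 * x1) * X1a
    if len(d2):
        value += np.sum(d2 * y2) / np.sum(d2 * x2) * X2a
    return value


def greg_estimator_direct(d1, y1, x1, d2, y2, x2, X1a, X2a):
    """Independent coding of the GREG form: HH total plus regression
    corrections with slope sum dxy / sum dx^2 per stratum."""
    a1 = np.sum(d1 * x1 * y1) / np.sum(d1 * x1 * x1)
    value = np.sum(d1 * y1) + a1 * (X1a - np.sum(d1 * x1))
    if len(d2):
        a2 = np.sum(d2 * x2 * y2) / np.sum(d2 * x2 * x2)
        value += np.sum(d2 * y2) + a2 * (X2a - np.sum(d2 * x2))
    return value


def bisect_exponential(d, x, target, lo=-200.0, hi=200.0, iters=200):
    """Brute-force bisection oracle for sum d x exp(l x) = target."""
    xmax = x.max()
    lo, hi = lo / xmax, hi / xmax

    def f(l):
        return np.sum(d * x * np.exp(l * x)) - target

    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestQWeights:
    def test_unit(self):
        np.testing.assert_array_equal(
            q_weights(np.array([1., 2., 4.]), "unit"), [1, 1, 1])

    def test_inverse_x(self):
        np.testing.assert_allclose(
            q_weights(np.array([1., 2., 4.]), "inverse_x"), [1, 0.5, 0.25])

    def test_zero_x_rejected(self):
        with pytest.raises(ValueError):
            q_weights(np.array([1.0, 0.0]), "inverse_x")

    def test_nonlinear_policy_redirected(self):
        with pytest.raises(ValueError, match="solver"):
            q_weights(np.array([1.0]), "exponential")


class TestLinearMultiplier:
    def test_hand_case(self):
        # d=(1,1), q=(1,1), x=(1,2), target=4: l=(4-3)/5=0.2, t=(1.2,1.4)
        d = q = np.ones(2)
        x = np.array([1.0, 2.0])
        l = solve_linear_multiplier(d, q, x, 4.0)
        assert l == pytest.approx(0.2)
        t = linear_calibrated_weights(d, q, x, l)
        np.testing.assert_allclose(t, [1.2, 1.4])
        assert np.sum(t * x) == pytest.approx(4.0, abs=1e-14)

    def test_consistent_target_gives_zero(self):
        d, x = np.array([2.0, 3.0]), np.array([1.5, 0.5])
        l = solve_linear_multiplier(d, np.ones(2), x, np.sum(d * x))
        assert l == 0.0
        np.testing.assert_array_equal(
            linear_calibrated_weights(d, np.ones(2), x, l), d)

    def test_zero_denominator_rejected(self):
        with pytest.raises(CalibrationError):
            solve_linear_multiplier(np.ones(2), np.zeros(2),
                                    np.ones(2), 4.0)


class TestNonlinearSolvers:
    def test_consistent_target_identities(self):
        d, x = np.array([1.0, 1.0]), np.array([1.0, 3.0])
        target = np.sum(d * x)
        l, _ = solve_exponential_multiplier(d, x, target)
        eta, _ = solve_power_parameter(d, x, target)
        assert l == pytest.approx(0.0, abs=1e-12)
        assert eta == pytest.approx(1.0, abs=1e-12)

    def test_single_unit_closed_forms(self):
        # exp(l) = 2 -> l = ln 2 ; x*eta^x = 2 eta^2 = 8 -> eta = 2
        l, _ = solve_exponential_multiplier(
            np.array([1.0]), np.array([1.0]), 2.0)
        assert l == pytest.approx(np.log(2), rel=1e-10)
        eta, _ = solve_power_parameter(
            np.array([1.0]), np.array([2.0]), 8.0)
        assert eta == pytest.approx(2.0, rel=1e-10)

    def test_large_target_converges(self):
        d, x = np.array([1.0, 1.0]), np.array([1.0, 3.0])
        target = 10 * np.sum(d * x)
        l, _ = solve_exponential_multiplier(d, x, target)
        assert l > 0
        resid = abs(np.sum(d * x * np.exp(l * x)) - target) / target
        assert resid <= 1e-10

    def test_agrees_with_bisection_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            d = rng.uniform(1, 5, 12)
            x = rng.lognormal(0, 1, 12)
            target = np.sum(d * x) * rng.uniform(0.2, 5.0)
            l, _ = solve_exponential_multiplier(d, x, target)
            assert l == pytest.approx(
                bisect_exponential(d, x, target), abs=1e-9 * (1 + abs(l)))

    @given(st.integers(0, 10_000), st.floats(0.2, 5.0))
    @settings(max_examples=40, deadline=None)
    def test_power_is_exp_of_linear_multiplier(self, seed, factor):
        rng = np.random.default_rng(seed)
        d = rng.uniform(1, 4, 8)
        x = rng.lognormal(0, 1, 8)
        target = factor * np.sum(d * x)
        l, _ = solve_exponential_multiplier(d, x, target)
        eta, _ = solve_power_parameter(d, x, target)
        assert eta == pytest.approx(np.exp(l), rel=1e-10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(CalibrationError):
            solve_exponential_multiplier(np.array([1.0]), np.array([1.0]), -1.0)
        with pytest.raises(CalibrationError):
            solve_exponential_multiplier(np.array([1.0]), np.array([-1.0]), 2.0)


class TestCalibrateStratum:
    @pytest.mark.parametrize("policy", ["unit", "inverse_x",
                                        "exponential", "power"])
    def test_constraint_satisfied(self, policy):
        rng = np.random.default_rng(3)
        d = np.full(15, 2.9)
        x = rng.lognormal(0, 1, 15) * 100
        target = 0.4 * np.sum(d * x)
        cal = calibrate_stratum(d, x, target, policy)
        assert cal.converged
        assert cal.residual <= 1e-10
        assert np.sum(cal.t * x) == pytest.approx(target, rel=1e-9)

    def test_negative_weights_counted_for_greg(self):
        # a target far below the weighted total drives linear weights < 0
        d = np.ones(5)
        x = np.array([1.0, 2.0, 3.0, 10.0, 20.0])
        cal = calibrate_stratum(d, x, 0.05 * np.sum(d * x), "unit")
        assert cal.n_negative > 0

    def test_nonlinear_weights_stay_positive(self):
        d = np.ones(5)
        x = np.array([1.0, 2.0, 3.0, 10.0, 20.0])
        for policy in ("exponential", "power"):
            cal = calibrate_stratum(d, x, 0.05 * np.sum(d * x), policy)
            assert (cal.t > 0).all()


class TestDomainEstimate:
    def test_ratio_hand_case(self):
        # respondents only; inverse_x with X1a=12 -> (12/6)*12 = 24
        d = np.ones(3)
        y = np.array([2.0, 4.0, 6.0])
        x = np.array([1.0, 2.0, 3.0])
        cal = calibrate_stratum(d, x, 12.0, "inverse_x")
        est = domain_estimate(y, cal.t, None, None, 1, "ratio")
        assert est.value == pytest.approx(24.0)

    def test_misaligned_vectors_rejected(self):
        with pytest.raises(ValueError):
            domain_estimate(np.ones(3), np.ones(2), None, None, 1, "base")


class TestEstimateAll:
    def test_reduction_identities_on_random_draws(self, study_frame, table1):
        """q=1 reproduces the explicit GREG form and q=1/x the ratio form,
        each coded independently, to 1e-10 relative."""
        rng = np.random.default_rng(17)
        for _ in range(25):
            r = draw_realization(study_frame, 70, 12, rng)
            d1 = np.full(r.n1, 203 / 70)
            d2 = np.full(r.n2r, (203 / 70) * r.k)
            y1, x1 = study_frame.y[r.s1], study_frame.x[r.s1]
            y2, x2 = study_frame.y[r.s2r], study_frame.x[r.s2r]
            ests = {(e.estimator, e.domain): e.value
                    for e in estimate_all(r, study_frame, table1,
                                          ("ratio", "greg"))}
            for dom in table1.domains:
                row = table1.row(dom)
                expect_ratio = ratio_estimator_direct(
                    d1, y1, x1, d2, y2, x2, row["X1a"], row["X2a"])
                expect_greg = greg_estimator_direct(
                    d1, y1, x1, d2, y2, x2, row["X1a"], row["X2a"])
                assert ests[("ratio", dom)] == pytest.approx(
                    expect_ratio, rel=1e-10)
                assert ests[("greg", dom)] == pytest.approx(
                    expect_greg, rel=1e-10)

    def test_all_estimators_finite_on_study_draw(self, study_frame, table1):
        r = draw_realization(study_frame, 70, 12, np.random.default_rng(4))
        ests = estimate_all(r, study_frame, table1)
        assert len(ests) == 5 * 6
        assert all(np.isfinite(e.value) for e in ests)

    def test_proportional_population_recovers_totals_exactly(
            self, proportional_frame):
        """With y = beta*x, every calibrated estimator returns Ya exactly."""
        totals = summarize_domains(proportional_frame)
        r = draw_realization(proportional_frame, 20, 3,
                             np.random.default_rng(2))
        for e in estimate_all(r, proportional_frame, totals,
                              ("ratio", "greg", "exponential", "power")):
            Ya = totals.row(e.domain)["Ya"]
            assert e.value == pytest.approx(Ya, rel=1e-9)

    def test_base_matches_hansen_hurwitz_per_domain(self, toy_frame):
        totals = summarize_domains(toy_frame)
        r = draw_realization(toy_frame, 15, 3, np.random.default_rng(0))
        base = {e.domain: e.value
                for e in estimate_all(r, toy_frame, totals, ("base",))}
        # summed over domains, the direct HH domain totals give the
        # population HH total
        assert sum(base.values()) == pytest.approx(
            hansen_hurwitz_total(r, toy_frame), rel=1e-12)

    def test_no_nonrespondents_sets_degenerate_flag(self, toy_frame):
        resp = np.flatnonzero(toy_frame.stratum == "R")
        from domcal import SampleRealization
        r = SampleRealization(s=resp[:10], s1=resp[:10],
                              s2=resp[:0], s2r=resp[:0], k=float("nan"))
        totals = summarize_domains(toy_frame)
        ests = estimate_all(r, toy_frame, totals, ("ratio", "power"))
        assert all(e.degenerate for e in ests)
        assert all(np.isfinite(e.value) for e in ests)
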