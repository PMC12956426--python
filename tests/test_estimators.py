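import numpy as np
import pandas as pd
import pytest

from qpipd import estimators as est
from qpipd.stepfun import StepFunction


def _basic_four():
    # events at 1, 2, 3 and one censoring at 1.5 among 4 subjects
    return np.array([1.0, 1.5, 2.0, 3.0]), np.array([1, 0, 1, 1])


def _exp_two_arm(seed, n=300, coarsen=None):
    rng = np.random.default_rng(seed)
    z = np.repeat([0, 1], n // 2)
    T = rng.exponential(1 / (0.3 * np.exp(-0.5 * z)))
    C = rng.uniform(2, 8, size=n)
    time = np.minimum(T, C)
    status = (T <= C).astype(int)
    if coarsen:
        time = np.ceil(time / coarsen) * coarsen
    return time, status, z


class TestKaplanMeier:
    def test_product_limit_values(self):
        t, s = _basic_four()
        km = est.kaplan_meier(t, s)
        assert km.sf(np.array([1.0, 2.0, 3.0])) == pytest.approx([0.75, 0.375, 0.0])

    def test_all_censored_flat(self):
        km = est.kaplan_meier([1.0, 2.0], [0, 0])
        assert km.sf(np.array([5.0])) == pytest.approx([1.0])

    def test_greenwood_first_term(self):
        t, s = _basic_four()
        km = est.kaplan_meier(t, s)
        # d/(r(r-d)) at the first event: 1/(4*3)
        assert km.se_log[0] ** 2 == pytest.approx(1 / 12)

    def test_matches_lifelines(self):
        import lifelines
        t, s, _ = _exp_two_arm(5, coarsen=0.25)
        km = est.kaplan_meier(t, s)
        lf = lifelines.KaplanMeierFitter().fit(t, s)
        grid = lf.survival_function_.index.values[1:]
        assert np.atleast_1d(km.sf(grid)) == pytest.approx(
            lf.survival_function_.values[1:, 0], abs=1e-12)

    def test_ci_ordering(self):
        t, s, _ = _exp_two_arm(6)
        km = est.kaplan_meier(t, s)
        grid = km.times
        lo, hi, mid = km.ci_lower(grid), km.ci_upper(grid), km.sf(grid)
        assert np.all(lo <= mid + 1e-12) and np.all(mid <= hi + 1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            est.kaplan_meier([], [])


class TestAalenJohansen:
    def test_three_subject_example(self):
        t = np.array([1.0, 2.0, 3.0])
        s = np.array([1, 2, 1])
        f1, f2 = est.aalen_johansen(t, s, 2)
        assert f1(t) == pytest.approx([1 / 3, 1 / 3, 2 / 3])
        assert f2(t) == pytest.approx([0.0, 1 / 3, 1 / 3])

    def test_single_cause_is_one_minus_km(self):
        t, s, _ = _exp_two_arm(7, coarsen=0.25)
        (f1,) = est.aalen_johansen(t, s, 1)
        km = est.kaplan_meier(t, s)
        grid = km.times
        assert np.atleast_1d(f1(grid)) == pytest.approx(1 - km.sf(grid), abs=1e-12)

    def test_all_censored_zero(self):
        (f1,) = est.aalen_johansen([1.0, 2.0], [0, 0], 1)
        assert f1(np.array([9.0])) == pytest.approx([0.0])

    def test_cifs_plus_survival_sum_to_one_without_censoring(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(1, 50)
        s = rng.integers(1, 3, 50)
        f1, f2 = est.aalen_johansen(t, s, 2)
        km = est.kaplan_meier(t, (s > 0).astype(int))
        grid = np.sort(t)
        total = np.atleast_1d(f1(grid)) + np.atleast_1d(f2(grid)) + km.sf(grid)
        assert total == pytest.approx(np.ones_like(grid))


class TestWeibull:
    def test_exponential_closed_form(self):
        fit = est.fit_weibull([1.0, 2.0, 3.0], [1, 1, 1], fixed_shape=1.0)
        assert fit.rate == pytest.approx(3 / 6)

    def test_parameter_recovery_large_n(self):
        rng = np.random.default_rng(12)
        alpha, lam, n = 0.8, 0.2, 20000
        t = (-np.log(rng.uniform(size=n))) ** (1 / alpha) / lam
        fit = est.fit_weibull(t, np.ones(n, dtype=int))
        se = np.sqrt(np.diag(fit.cov))
        assert abs(fit.log_rate - np.log(lam)) < 3 * se[0]
        assert abs(fit.log_shape - np.log(alpha)) < 3 * se[1]

    def test_all_censored_non_identifiable(self):
        with pytest.raises(est.ConvergenceError):
            est.fit_weibull([1.0, 2.0], [0, 0])


class TestCox:
    def test_matches_sksurv_breslow_with_ties(self):
        from sksurv.linear_model import CoxPHSurvivalAnalysis
        t, s, z = _exp_two_arm(42, coarsen=0.25)
        ours = est.fit_cox(t, s, z)
        y = np.array([(bool(e), ti) for e, ti in zip(s, t)],
                     dtype=[("e", bool), ("t", float)])
        ref = CoxPHSurvivalAnalysis(ties="breslow").fit(
            pd.DataFrame({"z": z.astype(float)}), y)
        assert ours.coef == pytest.approx(ref.coef_[0], abs=1e-8)

    def test_exchangeable_groups_near_zero(self):
        t, s, z = _exp_two_arm(13)
        rng = np.random.default_rng(13)
        fit = est.fit_cox(t, s, rng.permutation(z))
        assert abs(fit.coef) < 3 * fit.se

    def test_monotone_likelihood_detected(self):
        # complete separation: all group-1 events before any group-0 time
        t = np.array([1.0, 2.0, 10.0, 11.0])
        s = np.array([1, 1, 0, 0])
        z = np.array([1, 1, 0, 0])
        with pytest.raises(est.ConvergenceError):
            est.fit_cox(t, s, z)


class TestGrambschTherneau:
    def test_matches_r_coxzph_frozen(self):
        """Frozen oracle: survival::cox.zph(transform='identity') on this
        exact tie-free fixture gives 0.0430462302 (beta -0.6850785707)."""
        t, s, z = _exp_two_arm(7, n=120)
        fit = est.fit_cox(t, s, z)
        assert fit.coef == pytest.approx(-0.6850785707, abs=1e-7)
        stat = est.grambsch_therneau(t, s, z, fit)
        assert stat == pytest.approx(0.0430462302, abs=1e-6)

    def test_mean_near_one_under_proportional_hazards(self):
        rng = np.random.default_rng(99)
        stats = []
        for _ in range(400):
            n = 200
            z = np.repeat([0, 1], n // 2)
            T = rng.exponential(1 / (0.3 * np.exp(-0.5 * z)))
            C = rng.uniform(2, 8, n)
            t = np.minimum(T, C)
            s = (T <= C).astype(int)
            stats.append(est.grambsch_therneau(t, s, z))
        assert 0.85 < np.mean(stats) < 1.15

    def test_power_against_crossing_hazards(self):
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(40):
            n = 300
            z = np.repeat([0, 1], n // 2)
            # group-1 hazard switches from low to high at t=1 (strong drift)
            u = rng.uniform(size=n)
            h0, h1a, h1b = 0.5, 0.1, 2.0
            t0 = -np.log(u[z == 0]) / h0
            e = rng.exponential(size=(z == 1).sum())
            t1 = np.where(e < h1a, e / h1a, 1 + (e - h1a) / h1b)
            t = np.concatenate([t0, t1])
            zz = np.concatenate([np.zeros((z == 0).sum()), np.ones((z == 1).sum())])
            s = np.ones(n, dtype=int)
            if est.grambsch_therneau(t, s, zz) > 3.84:
                hits += 1
        assert hits >= 32   # >= 80% rejection


class TestRmst:
    def test_step_function_area(self):
        # S = 1 on [0,1), 0.5 on [1,5): RMST(5) = 1 + 4 * 0.5 = 3
        t = np.array([1.0, 1.0, 6.0, 6.0])
        s = np.array([1, 1, 0, 0])
        assert est.rmst(t, s, 5.0) == pytest.approx(3.0)

    def test_flat_curve_gives_horizon(self):
        assert est.rmst([9.0, 9.0], [0, 0], 5.0) == pytest.approx(5.0)

    def test_identical_arms_zero_difference(self):
        t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        s = np.array([1, 0, 1, 1, 0, 1])
        z = np.array([0, 0, 0, 1, 1, 1])
        assert est.rmst_difference(t, s, z, 5.0) == pytest.approx(0.0)


class TestCompetingRisks:
    def _fixture(self):
        rng = np.random.default_rng(11)
        n = 250
        z = np.repeat([0, 1], [125, 125])
        k, l01, a1, l02, a2, b1, b2 = 0.6, 0.4, 1.2, 0.2, 1.5, -0.3, 0.3
        g1 = np.exp(b1 * z)
        p1 = 1 - (1 - k) ** g1
        cause = (rng.uniform(size=n) < p1).astype(int)
        U = rng.uniform(size=n)
        inner = 1 - (1 - (1 - U * (1 - (1 - k) ** g1)) ** (1 / g1)) / k
        t1 = (-np.log(inner) / l01) ** (1 / a1)
        t2 = (-np.log(1 - rng.uniform(size=n)) / (l02 * np.exp(b2 * z))) ** (1 / a2)
        T = np.where(cause == 1, t1, t2)
        st = np.where(cause == 1, 1, 2)
        C = rng.uniform(1, 6, size=n)
        return np.minimum(T, C), np.where(T <= C, st, 0), z

    def test_fine_gray_matches_r_finegray_frozen(self):
        """Frozen oracle: survival::finegray + coxph(ties='breslow') on this
        exact fixture gives beta = -0.2963289767."""
        t, s, z = self._fixture()
        fit = est.fit_fine_gray(t, s, z, cause=1)
        assert fit.coef == pytest.approx(-0.2963289767, abs=1e-5)

    def test_cause_specific_matches_r_frozen(self):
        t, s, z = self._fixture()
        fit = est.fit_cause_specific_cox(t, s, z, cause=1)
        assert fit.coef == pytest.approx(-0.2309141078, abs=1e-8)

    def test_cause_specific_equals_cox_on_recoded(self):
        t, s, z = self._fixture()
        a = est.fit_cause_specific_cox(t, s, z, cause=2)
        b = est.fit_cox(t, (s == 2).astype(int), z)
        assert a.coef == pytest.approx(b.coef, abs=1e-12)

    def test_fine_gray_equals_cox_single_cause_no_censoring(self):
        rng = np.random.default_rng(3)
        n = 150
        z = np.repeat([0, 1], n // 2)
        t = rng.exponential(1 / (0.5 * np.exp(-0.4 * z)))
        s = np.ones(n, dtype=int)
        fg = est.fit_fine_gray(t, s, z, cause=1)
        cx = est.fit_cox(t, s, z)
        assert fg.coef == pytest.approx(cx.coef, abs=1e-8)

    def test_fine_gray_recovers_generator_coefficient(self):
        # larger sample: the cause-1 subdistribution model is correctly
        # specified with beta1 = -0.3
        rng = np.random.default_rng(77)
        n = 6000
        z = np.repeat([0, 1], n // 2)
        k, l01, a1, l02, a2, b1, b2 = 0.6, 0.4, 1.2, 0.2, 1.5, -0.3, 0.3
        g1 = np.exp(b1 * z)
        p1 = 1 - (1 - k) ** g1
        cause = (rng.uniform(size=n) < p1).astype(int)
        U = rng.uniform(size=n)
        inner = 1 - (1 - (1 - U * (1 - (1 - k) ** g1)) ** (1 / g1)) / k
        t1 = (-np.log(inner) / l01) ** (1 / a1)
        t2 = (-np.log(1 - rng.uniform(size=n)) / (l02 * np.exp(b2 * z))) ** (1 / a2)
        T = np.where(cause == 1, t1, t2)
        st = np.where(cause == 1, 1, 2)
        C = rng.uniform(1, 6, size=n)
        t = np.ceil(np.minimum(T, C) / 0.05) * 0.05
        s = np.where(T <= C, st, 0)
        fit = est.fit_fine_gray(t, s, z, cause=1)
        assert abs(fit.coef - (-0.3)) < 3 * fit.se


class TestRoundTripKm:
    def test_reconstructed_km_matches_digitized_curve(self):
        """Exact-information pseudo-IPD reproduces the input KM values."""
        from qpipd import reconstruct_km
        from qpipd.simulate import ScenarioConfig, simulate_truth
        from conftest import exact_channels
        cfg = ScenarioConfig(scenario="base", n_per_arm=60, base_seed=2)
        truth = simulate_truth(cfg, 0)
        curve, ticks, at_risk, ne = exact_channels(truth)
        rec = reconstruct_km(curve, at_risk=at_risk, ticks=ticks, total_events=ne)
        km = est.kaplan_meier(rec.ipd["time"], rec.ipd["status"])
        assert np.atleast_1d(km.sf(curve.times)) == pytest.approx(
            curve.values, abs=1e-12)
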