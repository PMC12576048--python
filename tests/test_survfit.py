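"""Survival estimators: hand oracles, external oracles, consistency, EM."""

import numpy as np
import pytest
from scipy import optimize, stats

from lbpseudo import (
    LBRCSample,
    influence_phi,
    ltrc_km,
    risk_indicator,
    risk_process,
    simulate_cohort,
    vardi_npmle,
    wang_estimator,
)
from lbpseudo.simulate import TrueModel


class Rec:
    def __init__(self, a, y, delta):
        self.a, self.y, self.delta = a, y, delta


class TestRiskIndicator:
    @pytest.mark.parametrize(
        "a, y, delta, t, expected",
        [
            (0.2, 1.0, 1, 0.9, 2),  # both the calendar and residual segments cover t
            (0.5, 0.8, 0, 0.6, 1),  # censored: only the calendar segment counts
            (0.1, 0.6, 1, 0.7, 0),  # past the observation: not at risk
            (0.5, 0.8, 0, 0.8, 1),  # censored exactly at t still counts
        ],
    )
    def test_cases(self, a, y, delta, t, expected):
        assert risk_indicator(Rec(a, y, delta), t) == expected


class TestProductLimitToy:
    def test_wang_hand_values(self, toy_sample):
        curve = wang_estimator(toy_sample)
        # at u=0.6: dH=1/3, R=(1+1+2)/6=2/3 -> factor 1/2; at u=1.0: R=2/6 -> 0
        assert curve(0.5) == pytest.approx(1.0)
        assert curve(0.6) == pytest.approx(0.5)
        assert curve(0.99) == pytest.approx(0.5)
        assert curve(1.0) == pytest.approx(0.0)

    def test_ltrc_hand_values(self, toy_sample):
        curve = ltrc_km(toy_sample)
        # risk sets: r(0.6)=3 -> 2/3; r(1.0)=1 -> 0
        assert curve(0.6) == pytest.approx(2.0 / 3.0)
        assert curve(1.0) == pytest.approx(0.0)

    def test_value_one_before_first_event(self, toy_sample):
        for est in (wang_estimator, ltrc_km, vardi_npmle):
            assert est(toy_sample)(0.1) == pytest.approx(1.0)

    def test_no_events_raises(self):
        s = LBRCSample(a=[0.1, 0.2], y=[1.0, 2.0], delta=[0, 0], x=np.zeros((2, 1)))
        with pytest.raises(ValueError):
            wang_estimator(s)


class TestRiskProcess:
    def test_counting_bounds(self, toy_sample):
        h_inf, _ = risk_process(toy_sample, 100.0)
        assert h_inf * toy_sample.n == toy_sample.delta.sum()
        _, r_after = risk_process(toy_sample, toy_sample.y.max() + 1.0)
        assert r_after == 0.0

    def test_population_identity_under_known_censoring(self, scenario1_null):
        """R_n(t) estimates S(t) w(t) / mu with w(t) = int_0^t G(u) du.

        Constant baseline, no covariate effects: S = e^{-2t}, mu = 1/2, and
        uniform(0,1) residual censoring gives w(t) = t - t^2/2.
        """
        sample = simulate_cohort(scenario1_null, 100_000, censor_scale=1.0, seed=13)
        for t in (0.4, 0.8):
            _, rn = risk_process(sample, t)
            w = t - t**2 / 2.0
            target = 2.0 * np.exp(-2.0 * t) * w
            # 3x MC error of the mean of R_i(t)/2
            ri = risk_indicator(sample, t) / 2.0
            assert abs(rn - target) < 3.0 * ri.std() / np.sqrt(sample.n)


class TestConsistency:
    def test_wang_converges_to_true_survival(self, scenario1_null):
        sample = simulate_cohort(scenario1_null, 20_000, censor_scale=None, seed=17)
        curve = wang_estimator(sample)
        grid = np.linspace(0.1, 1.0, 19)
        assert np.max(np.abs(curve(grid) - np.exp(-2.0 * grid))) < 0.03

    def test_ltrc_converges_to_true_survival(self, scenario1_null):
        sample = simulate_cohort(scenario1_null, 20_000, censor_scale=None, seed=18)
        curve = ltrc_km(sample)
        grid = np.linspace(0.3, 1.0, 15)
        assert np.max(np.abs(curve(grid) - np.exp(-2.0 * grid))) < 0.05

    def test_vardi_and_wang_agree_in_large_samples(self, scenario1, censor_scale_cache):
        c = censor_scale_cache("I", 0.25)
        sample = simulate_cohort(scenario1, 2000, censor_scale=c, seed=19)
        grid = np.arange(0.4, 1.301, 0.1)
        v = vardi_npmle(sample)(grid)
        w = wang_estimator(sample)(grid)
        assert np.max(np.abs(np.asarray(v) - np.asarray(w))) < 0.03


class TestAgainstLifelines:
    def test_ltrc_reduces_to_kaplan_meier_without_truncation(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(21)
        y = rng.exponential(1.0, 80)
        delta = rng.integers(0, 2, 80)
        delta[:4] = 1
        s = LBRCSample(a=np.zeros(80), y=y, delta=delta, x=np.zeros((80, 1)))
        km = KaplanMeierFitter().fit(y, delta)
        ours = ltrc_km(s)
        grid = np.quantile(y, [0.1, 0.3, 0.5, 0.7, 0.9])
        theirs = km.survival_function_at_times(grid).to_numpy()
        np.testing.assert_allclose(np.asarray(ours(grid)), theirs, atol=1e-12)

    def test_ltrc_matches_lifelines_late_entry(self, scenario1, censor_scale_cache):
        from lifelines import KaplanMeierFitter

        c = censor_scale_cache("I", 0.25)
        s = simulate_cohort(scenario1, 400, censor_scale=c, seed=22)
        km = KaplanMeierFitter().fit(s.y, s.delta, entry=s.a)
        ours = ltrc_km(s)
        grid = np.arange(0.4, 1.301, 0.1)
        theirs = km.survival_function_at_times(grid).to_numpy()
        np.testing.assert_allclose(np.asarray(ours(grid)), theirs, atol=1e-10)


def _vardi_loglik_independent(support, masses, events_y, cens_y):
    """Test-local NPMLE log-likelihood: events f_LB(y)/y, censored 1/x tail."""
    ll = 0.0
    q = masses / support
    for y in events_y:
        k = int(np.flatnonzero(support == y)[0])
        ll += np.log(masses[k] / y)
    for y in cens_y:
        tail = q[support > y].sum()
        ll += np.log(tail)
    return ll


class TestVardiNPMLE:
    def test_point_mass_when_single_event_time(self):
        s = LBRCSample(
            a=[0.1, 0.2, 0.1], y=[0.9, 0.9, 0.5], delta=[1, 1, 0], x=np.zeros((3, 1))
        )
        curve = vardi_npmle(s)
        assert curve(0.89) == pytest.approx(1.0)
        assert curve(0.9) == pytest.approx(0.0)
        np.testing.assert_allclose(curve.masses, [1.0])

    def test_toy_masses_and_inversion(self, toy_sample):
        # maximizing p1 * p2 * p2 on the simplex -> p = (1/3, 2/3);
        # 1/x inversion: q = (1/3/0.6, 2/3/1.0), S(0.6) = q2/(q1+q2) = 6/11
        curve = vardi_npmle(toy_sample, tol=1e-12)
        np.testing.assert_allclose(curve.masses, [1.0 / 3.0, 2.0 / 3.0], atol=1e-6)
        assert curve(0.6) == pytest.approx(6.0 / 11.0, abs=1e-6)

    def test_em_ascent(self, scenario1, censor_scale_cache):
        """The EM log-likelihood sequence is non-decreasing."""
        from lbpseudo.survfit import _event_table, _vardi_em_arrays

        c = censor_scale_cache("I", 0.50)
        s = simulate_cohort(scenario1, 120, censor_scale=c, seed=23)
        support, d = _event_table(s)
        cens_idx, _ = _vardi_em_arrays(support, d, s.y[s.delta == 0])
        p = np.full(support.size, 1.0 / support.size)
        lls = []
        for _ in range(60):
            q = p / support
            tail = np.concatenate([np.cumsum(q[::-1])[::-1], [0.0]])
            ti = tail[cens_idx]
            lls.append(float(d @ np.log(p) + np.sum(np.log(ti))))
            w = np.bincount(cens_idx, weights=1.0 / ti, minlength=support.size)
            p = (d + q * np.cumsum(w)) / (d.sum() + cens_idx.size)
        assert np.all(np.diff(lls) > -1e-10)

    @pytest.mark.parametrize("seed", [31, 32, 33])
    def test_em_matches_direct_simplex_maximization(self, seed):
        """On n <= 8 the EM solution attains the simplex maximum to 1e-6."""
        rng = np.random.default_rng(seed)
        n = 8
        a = rng.uniform(0, 0.3, n)
        y = a + rng.uniform(0.1, 1.0, n)
        delta = np.array([1, 1, 1, 0, 1, 0, 1, 1])
        order = np.argsort(y)
        y, a, delta = y[order], a[order], delta[order]
        delta[-1] = 1  # keep every censored subject below the last event
        s = LBRCSample(a=a, y=y, delta=delta, x=np.zeros((n, 1)))

        fit = vardi_npmle(s, tol=1e-13, max_iter=200_000)
        events_y = s.y[s.delta == 1]
        cens_y = s.y[s.delta == 0]
        ll_em = _vardi_loglik_independent(fit.support, fit.masses, events_y, cens_y)

        k = fit.support.size

        def neg_ll(z):
            p = np.exp(z - z.max())
            p = p / p.sum()
            return -_vardi_loglik_independent(fit.support, p, events_y, cens_y)

        best = np.inf
        for trial in range(5):
            z0 = rng.normal(size=k)
            res = optimize.minimize(neg_ll, z0, method="Nelder-Mead",
                                    options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 50_000})
            best = min(best, res.fun)
        assert ll_em >= -best - 1e-6
        assert ll_em <= -best + 1e-5  # the optimizer should agree, not undershoot


class TestInfluenceFunction:
    def test_mean_zero_large_sample(self, scenario1):
        sample = simulate_cohort(scenario1, 5000, censor_scale=None, seed=41)
        phi = influence_phi(sample, 0.8)
        assert abs(phi.mean()) < 0.02

    def test_first_term_vanishes_beyond_t(self, toy_sample):
        phi = influence_phi(toy_sample, 0.7)
        # subject 0 (y=1.0 > t) and subject 1 (censored) have first term 0,
        # so their phi values are the shared negative integral term
        assert phi[0] == pytest.approx(phi[1])
        assert phi[0] < 0 < phi[2]

    def test_linearization_remainder_shrinks_fast(self, scenario1_null):
        """The remainder of the first-order expansion decays faster than
        root-n: quadrupling n shrinks its mean magnitude by more than half."""
        t = 0.8
        s_true = np.exp(-2.0 * t)

        def remainder(n, seed):
            s = simulate_cohort(scenario1_null, n, censor_scale=None, seed=seed)
            phi = influence_phi(s, t)
            return abs(float(wang_estimator(s)(t)) - (s_true - s_true * phi.mean()))

        r500 = np.mean([remainder(500, 3000 + i) for i in range(40)])
        r2000 = np.mean([remainder(2000, 4000 + i) for i in range(40)])
        assert r2000 / r500 < 0.5


class TestCurveProperties:
    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_unit_interval(self, seed, scenario1, censor_scale_cache):
        c = censor_scale_cache("I", 0.25)
        s = simulate_cohort(scenario1, 60, censor_scale=c, seed=500 + seed)
        grid = np.linspace(0.01, s.y.max() + 0.5, 60)
        for est in (wang_estimator, ltrc_km, vardi_npmle):
            vals = np.asarray(est(s)(grid))
            assert np.all(vals <= 1.0 + 1e-12) and np.all(vals >= -1e-12)
            assert np.all(np.diff(vals) <= 1e-12)

    def test_serialization_roundtrip(self, toy_sample, tmp_path):
        curve = wang_estimator(toy_sample)
        df = curve.to_frame()
        assert df.iloc[0].tolist() == [0.0, 1.0]
        path = tmp_path / "curve.csv"
        df.to_csv(path, index=False)
        import pandas as pd

        back = pd.read_csv(path)
        np.testing.assert_allclose(back["survival"], df["survival"])
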