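import math

import numpy as np
import pytest
from scipy import stats

from cerna_screen import (
    SimulationConfig,
    SubjectRecord,
    cox_fit,
    dichotomize,
    km_estimate,
    logrank_test,
    simulate_cohort,
    spearman_rho,
    survival_at,
)
from cerna_screen.survival import _cox_loglik


def subjects(times, events, expr=None):
    return [
        SubjectRecord(
            f"s{i}",
            float(t),
            int(e),
            {"g": float(expr[i])} if expr is not None else {},
        )
        for i, (t, e) in enumerate(zip(times, events))
    ]


def random_cohort(rng, n=60, beta=0.0):
    x = rng.standard_normal(n)
    t = rng.exponential(1.0 / (0.05 * np.exp(beta * x)))
    e = (rng.random(n) < 0.75).astype(int)
    return subjects(t, e, x), x


class TestKmEstimate:
    def test_forced_three_events(self):
        curve = km_estimate(subjects([1, 2, 3], [1, 1, 1]))
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_survival_one(self):
        curve = km_estimate(subjects([1, 2, 3], [0, 0, 0]))
        assert curve.times.size == 0
        assert survival_at(curve, 100.0) == 1.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            km_estimate([])

    def test_eight_subject_hand_oracle(self):
        """Mixed events/censorings; S computed by an independent risk-set
        product written out longhand."""
        times = [2, 3, 3, 5, 7, 7, 9, 11]
        events = [1, 1, 0, 1, 1, 0, 0, 1]
        curve = km_estimate(subjects(times, events))
        # hand computation:
        # t=2: n=8 d=1 -> 7/8
        # t=3: n=7 d=1 -> 7/8 * 6/7 = 3/4 (one censored at 3 leaves after)
        # t=5: n=5 d=1 -> 3/4 * 4/5 = 3/5
        # t=7: n=4 d=1 -> 3/5 * 3/4 = 9/20
        # t=11: n=1 d=1 -> 0
        np.testing.assert_allclose(curve.times, [2, 3, 5, 7, 11])
        np.testing.assert_allclose(
            curve.survival, [7 / 8, 3 / 4, 3 / 5, 9 / 20, 0.0]
        )
        np.testing.assert_array_equal(curve.at_risk, [8, 7, 5, 4, 1])

    def test_monotone_nonincreasing(self, rng):
        for _ in range(20):
            recs, _ = random_cohort(rng)
            surv = km_estimate(recs).survival
            assert np.all(np.diff(surv) <= 1e-12)
            assert np.all((surv >= 0) & (surv <= 1))

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        recs, _ = random_cohort(rng, n=80)
        curve = km_estimate(recs)
        kmf = KaplanMeierFitter().fit(
            [r.time for r in recs], [r.event for r in recs]
        )
        for t in [1.0, 5.0, 10.0, 25.0, 60.0]:
            assert survival_at(curve, t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-10
            )


class TestSurvivalAt:
    def test_t_zero_is_one(self):
        curve = km_estimate(subjects([5], [1]))
        assert survival_at(curve, 0.0) == 1.0

    def test_beyond_last_time(self):
        curve = km_estimate(subjects([1, 2], [1, 0]))
        assert survival_at(curve, 99.0) == curve.survival[-1]

    def test_negative_t_errors(self):
        curve = km_estimate(subjects([1], [1]))
        with pytest.raises(ValueError):
            survival_at(curve, -1.0)

    def test_empirical_fraction_no_censoring(self, rng):
        times = rng.exponential(10, size=200)
        recs = subjects(times, np.ones(200))
        curve = km_estimate(recs)
        for t in [2.0, 8.0, 20.0]:
            assert survival_at(curve, t) == pytest.approx(
                float(np.mean(times > t)), abs=1e-12
            )


class TestLogRank:
    def test_identical_groups(self):
        recs = subjects([1, 2, 3, 4], [1, 1, 0, 1])
        res = logrank_test(recs, recs)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_two_groups_of_four_hand_sum(self):
        """Hand-summed O-E and hypergeometric V for a 2x4 example."""
        a = subjects([1, 3, 5, 7], [1, 1, 1, 0])
        b = subjects([2, 4, 6, 8], [1, 0, 1, 1])
        # event times 1,2,3,5,6,8; longhand:
        # t=1: n=8 na=4 d=1 da=1 -> E+=.5, V+=.25
        # t=2: n=7 na=3 d=1 da=0 -> E+=3/7, V+=(3/7)(4/7)
        # t=3: n=6 na=3 d=1 da=1 -> E+=.5, V+=.25
        # t=5: n=4 na=2 d=1 da=1 -> E+=.5, V+=.25
        # t=6: n=3 na=1 d=1 da=0 -> E+=1/3, V+=(1/3)(2/3)
        # t=8: n=1 na=0 d=1 da=0 -> E+=0, V+=0
        e_a = 0.5 + 3 / 7 + 0.5 + 0.5 + 1 / 3
        v = 0.25 * 3 + (3 / 7) * (4 / 7) + (1 / 3) * (2 / 3)
        o_a = 3.0
        res = logrank_test(a, b)
        assert res.observed[0] == pytest.approx(o_a)
        assert res.expected[0] == pytest.approx(e_a)
        assert res.chi_square == pytest.approx((o_a - e_a) ** 2 / v)
        assert res.p_value == pytest.approx(
            float(stats.chi2.sf((o_a - e_a) ** 2 / v, 1))
        )

    def test_no_events_errors(self):
        with pytest.raises(ValueError):
            logrank_test(subjects([1], [0]), subjects([2], [0]))

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            logrank_test([], subjects([1], [1]))

    def test_relabel_invariance(self, rng):
        for _ in range(10):
            a, _ = random_cohort(rng, n=30)
            b, _ = random_cohort(rng, n=25)
            r1 = logrank_test(a, b)
            r2 = logrank_test(b, a)
            assert r1.chi_square == pytest.approx(r2.chi_square, abs=1e-10)
            assert r1.p_value == pytest.approx(r2.p_value, abs=1e-10)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        for _ in range(5):
            a, _ = random_cohort(rng, n=40, beta=0.5)
            b, _ = random_cohort(rng, n=35)
            res = logrank_test(a, b)
            ll = ll_logrank(
                [r.time for r in a], [r.time for r in b],
                [r.event for r in a], [r.event for r in b],
            )
            assert res.chi_square == pytest.approx(ll.test_statistic, rel=1e-6)
            assert res.p_value == pytest.approx(ll.p_value, rel=1e-6)

    def test_permutation_null_uniform(self, rng):
        """Permuting group labels yields an approximately uniform p-value."""
        recs, _ = random_cohort(rng, n=50)
        n_a = 25
        pvals = []
        for _ in range(300):
            perm = rng.permutation(len(recs))
            a = [recs[i] for i in perm[:n_a]]
            b = [recs[i] for i in perm[n_a:]]
            pvals.append(logrank_test(a, b).p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 1e-3


class TestCoxFit:
    def test_constant_covariate_errors(self):
        recs = subjects([1, 2, 3], [1, 1, 1], [5.0, 5.0, 5.0])
        with pytest.raises(ValueError, match="constant"):
            cox_fit(recs, ["g"])

    def test_missing_covariate_errors(self):
        recs = subjects([1, 2], [1, 1], [0.0, 1.0])
        with pytest.raises(KeyError):
            cox_fit(recs, ["nope"])

    def test_null_beta_small(self):
        cfg = SimulationConfig(seed=5, beta=0.0, n_patients=1000, censor_rate=0.2)
        cohort, truth = simulate_cohort(cfg)
        res = cox_fit(cohort, [truth.core_gene])
        assert res.converged
        assert abs(res.beta[0]) < 0.1

    def test_recovers_beta(self):
        cfg = SimulationConfig(seed=2, beta=0.8, n_patients=1500, censor_rate=0.2)
        cohort, truth = simulate_cohort(cfg)
        res = cox_fit(cohort, [truth.core_gene])
        assert res.converged
        assert res.beta[0] == pytest.approx(0.8, abs=0.12)
        lo, hi = res.ci95
        assert lo[0] <= res.hr[0] <= hi[0]
        assert res.hr[0] > 1

    def test_matches_lifelines(self, rng):
        import pandas as pd
        from lifelines import CoxPHFitter

        recs, x = random_cohort(rng, n=120, beta=0.7)
        res = cox_fit(recs, ["g"])
        df = pd.DataFrame(
            {"T": [r.time for r in recs], "E": [r.event for r in recs], "g": x}
        )
        cph = CoxPHFitter().fit(df, "T", "E")
        assert res.beta[0] == pytest.approx(cph.params_["g"], abs=1e-5)
        assert res.se[0] == pytest.approx(cph.standard_errors_["g"], abs=1e-5)

    def test_partial_likelihood_nondecreasing(self, rng):
        recs, _ = random_cohort(rng, n=80, beta=0.6)
        res = cox_fit(recs, ["g"])
        X = np.array([[r.expr["g"]] for r in recs])
        t = np.array([r.time for r in recs])
        e = np.array([r.event for r in recs])
        ll_hat, _, _ = _cox_loglik(res.beta, X, t, e)
        ll_zero, _, _ = _cox_loglik(np.zeros(1), X, t, e)
        assert ll_hat >= ll_zero - 1e-9


class TestSpearman:
    def test_increasing(self):
        rho, p = spearman_rho([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == 1.0 and p == 0.0

    def test_reversed(self):
        rho, _ = spearman_rho([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == -1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2, 3], [1, 2])

    def test_too_short(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [1, 2])

    def test_tied_data_matches_scipy_oracle(self, rng):
        for _ in range(30):
            x = rng.integers(0, 5, size=25).astype(float)  # heavy ties
            y = rng.integers(0, 5, size=25).astype(float)
            if np.unique(x).size < 2 or np.unique(y).size < 2:
                continue
            rho, p = spearman_rho(x, y)
            want = stats.spearmanr(x, y)
            assert rho == pytest.approx(want.statistic, abs=1e-12)
            assert p == pytest.approx(want.pvalue, abs=1e-8)


class TestDichotomize:
    def test_median_split(self):
        assert dichotomize([1, 2, 3, 4], "median") == ["low", "low", "high", "high"]

    def test_median_ties_go_low(self):
        assert dichotomize([1, 2, 2, 4], "median") == ["low", "low", "low", "high"]

    def test_cutoff_below_min_all_high(self):
        assert dichotomize([5, 6, 7], -10.0) == ["high"] * 3

    def test_identical_values_error(self):
        with pytest.raises(ValueError):
            dichotomize([3, 3, 3], "median")

    def test_youden_agrees_with_exhaustive_search(self, rng):
        values = rng.normal(size=100)
        outcomes = (rng.random(100) < stats.norm.cdf(values)).astype(int)
        if outcomes.min() == outcomes.max():
            outcomes[0] = 1 - outcomes[0]
        labels = dichotomize(values, "youden", outcomes=outcomes)
        best_j, best_c = -np.inf, None
        for c in sorted(set(values)):  # exhaustive independent search
            pred = values >= c
            sens = (pred & (outcomes == 1)).sum() / (outcomes == 1).sum()
            spec = (~pred & (outcomes == 0)).sum() / (outcomes == 0).sum()
            if sens + spec - 1 > best_j + 1e-12:
                best_j, best_c = sens + spec - 1, c
        assert labels == ["high" if v >= best_c else "low" for v in values]
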