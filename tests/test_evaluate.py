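import numpy as np
import pytest
from scipy import stats

import pathsurv as ps


def make_surv(times, events):
    ids = [f"s{i}" for i in range(len(times))]
    return ps.SurvivalTable(ids, np.asarray(times, float), np.asarray(events, int))


def brute_force_cindex(eta, t, d):
    """O(n^2) literal pair enumeration of the concordance formula."""
    num = den = 0
    n = len(eta)
    for i in range(n):
        for j in range(n):
            if t[i] > t[j] and d[j] == 1:
                den += 1
                if eta[i] < eta[j]:
                    num += 1
    return num / den, den


class TestConcordance:
    def test_three_patient_worked_example(self):
        surv = make_surv([3, 5, 8], [1, 1, 0])
        pi = ps.PrognosticIndex(surv.sample_ids, [2.0, 3.0, 0.5])
        res = ps.concordance_index(pi, surv)
        assert res.n_comparable_pairs == 3
        assert res.c_index == pytest.approx(2 / 3)

    def test_perfect_and_inverted_endpoints(self):
        rng = np.random.default_rng(0)
        t = rng.permutation(50) + 1.0
        surv = make_surv(t, np.ones(50))
        good = ps.PrognosticIndex(surv.sample_ids, -t)
        bad = ps.PrognosticIndex(surv.sample_ids, t.astype(float))
        assert ps.concordance_index(good, surv).c_index == 1.0
        assert ps.concordance_index(bad, surv).c_index == 0.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(1, 1000)
        surv = make_surv(t, (rng.random(1000) < 0.7).astype(int))
        pi = ps.PrognosticIndex(surv.sample_ids, rng.standard_normal(1000))
        assert abs(ps.concordance_index(pi, surv).c_index - 0.5) < 0.03

    def test_single_patient_raises(self):
        surv = make_surv([1.0], [1])
        pi = ps.PrognosticIndex(surv.sample_ids, [0.0])
        with pytest.raises(ValueError, match="comparable"):
            ps.concordance_index(pi, surv)

    @pytest.mark.parametrize("n", [5, 23, 87, 200])
    def test_matches_brute_force_enumeration(self, n):
        rng = np.random.default_rng(n)
        t = rng.choice(np.arange(1, n), size=n).astype(float)  # ties likely
        d = rng.integers(0, 2, n)
        d[rng.integers(n)] = 1
        eta = np.round(rng.standard_normal(n), 1)  # score ties likely
        surv = make_surv(t, d)
        res = ps.concordance_index(ps.PrognosticIndex(surv.sample_ids, eta), surv)
        expect, pairs = brute_force_cindex(eta, t, d)
        assert res.n_comparable_pairs == pairs
        assert res.c_index == pytest.approx(expect)

    def test_complement_identity_without_score_ties(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(1, 60)
        surv = make_surv(t, (rng.random(60) < 0.6).astype(int))
        eta = rng.standard_normal(60)
        c1 = ps.concordance_index(ps.PrognosticIndex(surv.sample_ids, eta), surv).c_index
        c2 = ps.concordance_index(ps.PrognosticIndex(surv.sample_ids, -eta), surv).c_index
        assert c1 + c2 == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(1, 40)
        surv = make_surv(t, np.ones(40))
        eta = rng.standard_normal(40)
        c1 = ps.concordance_index(ps.PrognosticIndex(surv.sample_ids, eta), surv).c_index
        c2 = ps.concordance_index(
            ps.PrognosticIndex(surv.sample_ids, np.exp(3 * eta)), surv).c_index
        assert c1 == pytest.approx(c2)

    def test_agrees_with_scikit_survival_when_untied(self):
        from sksurv.metrics import concordance_index_censored
        rng = np.random.default_rng(5)
        t = rng.exponential(1, 80) + rng.random(80) * 1e-6  # no time ties
        d = (rng.random(80) < 0.7)
        d[0] = True
        eta = rng.standard_normal(80)
        surv = make_surv(t, d.astype(int))
        ours = ps.concordance_index(ps.PrognosticIndex(surv.sample_ids, eta), surv)
        # same convention: higher risk score concordant with shorter time
        theirs = concordance_index_censored(d, t, eta)[0]
        assert ours.c_index == pytest.approx(theirs)


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        km = ps.km_estimate(make_surv([1, 2, 3], [0, 0, 0]))
        assert km.survival_at(10.0) == 1.0

    def test_three_events_product_limit(self):
        km = ps.km_estimate(make_surv([1, 2, 3], [1, 1, 1]))
        assert np.allclose(km.event_times, [1, 2, 3])
        assert np.allclose(km.survival_prob, [2 / 3, 1 / 3, 0])
        assert np.array_equal(km.at_risk, [3, 2, 1])

    def test_step_function_right_continuous_and_monotone(self):
        rng = np.random.default_rng(6)
        km = ps.km_estimate(make_surv(rng.exponential(1, 50),
                                      (rng.random(50) < 0.7).astype(int)))
        assert np.all(np.diff(km.survival_prob) <= 1e-12)
        assert km.survival_at(0.0) <= 1.0
        t0 = km.event_times[0]
        assert km.survival_at(t0) == km.survival_prob[0]  # right continuity
        assert km.survival_at(t0 - 1e-9) == 1.0


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([1.0, 2, 3, 4, 5])
        e = np.array([1, 0, 1, 1, 0])
        surv = make_surv(np.r_[t, t], np.r_[e, e])
        groups = ps.RiskGroups(pi_med=0.0, sample_ids=surv.sample_ids,
                               labels=["high"] * 5 + ["low"] * 5)
        res = ps.logrank_test(groups, surv)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_toy_example_matches_hypergeometric_brute_force(self):
        t = np.array([1.0, 2, 3, 4, 5, 6])
        e = np.array([1, 1, 1, 1, 1, 0])
        labels = ["high", "high", "low", "high", "low", "low"]
        surv = make_surv(t, e)
        groups = ps.RiskGroups(0.0, surv.sample_ids, labels)
        res = ps.logrank_test(groups, surv)
        # brute force: one 2x2 table per distinct event time
        hi = np.array([lab == "high" for lab in labels])
        O = E = V = 0.0
        for tt in np.unique(t[e == 1]):
            at_risk = t >= tt
            n = at_risk.sum()
            n1 = (at_risk & hi).sum()
            d = ((t == tt) & (e == 1)).sum()
            o1 = ((t == tt) & (e == 1) & hi).sum()
            O += o1
            E += d * n1 / n
            if n > 1:
                V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        expected = (O - E) ** 2 / V
        assert res.statistic == pytest.approx(expected, rel=1e-6)

    def test_strong_separation_is_significant(self):
        rng = np.random.default_rng(7)
        t_hi = rng.exponential(0.3, 40)
        t_lo = rng.exponential(3.0, 40)
        surv = make_surv(np.r_[t_hi, t_lo], np.ones(80))
        groups = ps.RiskGroups(0.0, surv.sample_ids,
                               ["high"] * 40 + ["low"] * 40)
        assert ps.logrank_test(groups, surv).p_value < 0.05

    def test_single_group_raises(self):
        surv = make_surv([1.0, 2.0], [1, 1])
        groups = ps.RiskGroups(0.0, surv.sample_ids, ["high", "high"])
        with pytest.raises(ValueError):
            ps.logrank_test(groups, surv)

    def test_null_rejection_rate_is_calibrated(self):
        """Under identical group survival, the log-rank test rejects at close
        to its nominal 5% level (2000 simulated cohorts)."""
        rng = np.random.default_rng(8)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            t = rng.exponential(1, 40)
            e = (rng.random(40) < 0.7).astype(int)
            labels = np.where(rng.random(40) < 0.5, "high", "low")
            if len(set(labels)) < 2 or e.sum() == 0:
                continue
            surv = make_surv(t, e)
            g = ps.RiskGroups(0.0, surv.sample_ids, list(labels))
            if ps.logrank_test(g, surv).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07


class TestWilcoxon:
    def test_equal_vectors_p_one(self):
        with pytest.warns(UserWarning, match="zero"):
            res = ps.wilcoxon_signed_rank([1.0, 2, 3, 4, 5], [1.0, 2, 3, 4, 5])
        assert res.p_value == 1.0

    def test_exact_p_for_six_positive_differences(self):
        res = ps.wilcoxon_signed_rank([2.0, 3, 4, 5, 6, 7], [1.0] * 6)
        assert res.p_value == pytest.approx(2 / 64)
        assert "exact" in res.method

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(9)
        a = rng.standard_normal(40)
        res = ps.wilcoxon_signed_rank(a + 0.5, a)
        assert "approx" in res.method
        assert res.p_value < 0.05

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            ps.wilcoxon_signed_rank([1.0, 2.0], [1.0])


class TestUnivariateCox:
    def test_independent_covariate_hr_near_one(self):
        rng = np.random.default_rng(10)
        n = 2000
        x = (rng.random(n) < 0.5).astype(float)
        surv = make_surv(rng.exponential(1, n), np.ones(n))
        res = ps.univariate_cox(x, surv)
        assert abs(res.hazard_ratio - 1) < 0.15
        assert res.ci_lower < res.hazard_ratio < res.ci_upper

    def test_four_patient_fit_matches_grid_search_oracle(self):
        x = np.array([1.0, 0.0, 1.0, 0.0])
        surv = make_surv([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 0])
        res = ps.univariate_cox(x, surv)
        from pathsurv.survnet import cox_partial_loss
        grid = np.arange(-5, 5, 1e-4)
        nll = [cox_partial_loss(b * x, surv.time, surv.event) for b in grid]
        beta_star = grid[int(np.argmin(nll))]
        assert res.coef == pytest.approx(beta_star, abs=1e-4)

    def test_detects_real_effect(self):
        rng = np.random.default_rng(11)
        n = 600
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(np.exp(-1.0 * x))
        surv = make_surv(t, np.ones(n))
        res = ps.univariate_cox(x, surv)
        assert res.p_value < 1e-6
        assert res.hazard_ratio > 1.5


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert ps.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_hand_computed_step_up(self):
        adj = ps.bh_adjust([0.01, 0.02, 0.04])
        assert np.allclose(adj, [0.03, 0.03, 0.04])

    def test_never_below_raw_and_capped(self):
        rng = np.random.default_rng(12)
        p = rng.random(30)
        adj = ps.bh_adjust(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)


class TestSchoenfeld:
    def test_reference_event_counts_reproduce_power_bounds(self):
        up_ov, lo_ov = ps.schoenfeld_detectable_hr(222, alpha=0.05, power=0.8)
        up_br, lo_br = ps.schoenfeld_detectable_hr(175, alpha=0.05, power=0.8)
        assert round(up_ov, 2) == 1.21
        assert round(lo_br, 2) == 0.81

    def test_bounds_are_exact_reciprocals(self):
        up, lo = ps.schoenfeld_detectable_hr(137)
        assert lo == pytest.approx(1 / up, rel=1e-12)

    def test_closed_form(self):
        up, _ = ps.schoenfeld_detectable_hr(100, alpha=0.05, power=0.8)
        expected = np.exp((stats.norm.ppf(0.975) + stats.norm.ppf(0.8)) / 10.0)
        assert up == pytest.approx(expected)
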