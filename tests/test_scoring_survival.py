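"""Scores, ratios, KM/log-rank/cutpoint/Cox and group tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foltme import scoring_survival as ss


def _counts(rows):
    return pd.DataFrame(rows, columns=["patient_id", "roi_id", "marker",
                                       "compartment", "count"])


class TestMedianScore:
    def test_even_count_median_is_midpoint(self):
        tbl = _counts([("P1", f"r{i}", "CD68", "IF", c)
                       for i, c in enumerate([30, 35])])
        out = ss.patient_median_score(tbl, "CD68", "IF")
        assert out["value"].iloc[0] == 32.5

    def test_constant_counts_median(self):
        tbl = _counts([("P1", f"r{i}", "CD68", "IF", 40)
                       for i in range(10)])
        out = ss.patient_median_score(tbl, "CD68", "IF")
        assert out["value"].iloc[0] == 40
        assert out["n_rois"].iloc[0] == 10

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 150), min_size=1, max_size=12))
    def test_matches_bruteforce_sort_and_pick(self, counts):
        tbl = _counts([("P1", f"r{i}", "M", "EF", c)
                       for i, c in enumerate(counts)])
        out = ss.patient_median_score(tbl, "M", "EF")
        srt = sorted(counts)
        n = len(srt)
        brute = (srt[n // 2] if n % 2
                 else (srt[n // 2 - 1] + srt[n // 2]) / 2)
        assert out["value"].iloc[0] == brute


class TestMarkerRatio:
    def test_constant_ratio(self):
        rows = []
        for i in range(10):
            rows += [("P1", f"r{i}", "CD163", "EF", 8),
                     ("P1", f"r{i}", "CD8", "EF", 50)]
        out = ss.marker_ratio(_counts(rows), "CD163", "CD8", "EF")
        assert out["value"].iloc[0] == 16.0

    def test_equal_markers_ratio_100(self):
        rows = []
        for i in range(4):
            rows += [("P1", f"r{i}", "A", "EF", 7), ("P1", f"r{i}", "B", "EF", 7)]
        out = ss.marker_ratio(_counts(rows), "A", "B", "EF")
        assert out["value"].iloc[0] == 100.0

    def test_zero_denominator_rois_excluded_and_flagged(self):
        rows = [("P1", "r0", "A", "EF", 5), ("P1", "r0", "B", "EF", 0),
                ("P1", "r1", "A", "EF", 5), ("P1", "r1", "B", "EF", 10)]
        out = ss.marker_ratio(_counts(rows), "A", "B", "EF")
        assert out["n_rois"].iloc[0] == 1
        assert out["n_excluded"].iloc[0] == 1
        assert out["value"].iloc[0] == 50.0

    def test_all_zero_denominator_raises(self):
        rows = [("P1", "r0", "A", "EF", 5), ("P1", "r0", "B", "EF", 0)]
        with pytest.raises(ValueError):
            ss.marker_ratio(_counts(rows), "A", "B", "EF")

    def test_matches_bruteforce_per_roi(self, rng):
        rows = []
        num = rng.integers(0, 30, 10)
        den = rng.integers(1, 60, 10)
        for i in range(10):
            rows += [("P1", f"r{i}", "A", "EF", int(num[i])),
                     ("P1", f"r{i}", "B", "EF", int(den[i]))]
        out = ss.marker_ratio(_counts(rows), "A", "B", "EF")
        brute = float(np.median([100.0 * a / b for a, b in zip(num, den)]))
        assert out["value"].iloc[0] == brute


class TestClassifyHighLow:
    @pytest.mark.parametrize("value,cut,expected", [
        (16.25, 16.25, "high"), (16.24, 16.25, "low"),
        (18.0, 18.0, "high"), (32.5, 32.5, "high"), (53.74, 53.75, "low"),
    ])
    def test_boundary_convention(self, value, cut, expected):
        assert ss.classify_high_low(value, cut) == expected


class TestKaplanMeier:
    def test_two_events_product_limit(self):
        curve = ss.km_estimate([5.0, 10.0], [1, 1])
        s5, _ = ss.survival_at(curve, 5.0)
        s10, _ = ss.survival_at(curve, 10.0)
        assert s5 == 0.5 and s10 == 0.0

    def test_all_censored_survival_is_one(self):
        curve = ss.km_estimate([3.0, 6.0, 9.0], [0, 0, 0])
        assert ss.survival_at(curve, 100.0)[0] == 1.0

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(10, 200)
        curve = ss.km_estimate(t, np.ones(200, int))
        for q in (2.0, 5.0, 15.0):
            s, _ = ss.survival_at(curve, q)
            assert s == pytest.approx((t > q).mean(), abs=1e-12)

    def test_greenwood_variance_matches_bruteforce(self, rng):
        t = rng.exponential(10, 60)
        e = (rng.random(60) < 0.7).astype(int)
        curve = ss.km_estimate(t, e)
        for i, u in enumerate(curve.event_times):
            acc = 0.0
            for v in curve.event_times[curve.event_times <= u]:
                n_at = (t >= v).sum()
                d = ((t == v) & (e == 1)).sum()
                if n_at > d:
                    acc += d / (n_at * (n_at - d))
            assert curve.variance[i] == pytest.approx(
                curve.survival[i] ** 2 * acc)

    def test_against_lifelines_oracle(self, rng):
        lifelines = pytest.importorskip("lifelines")
        t = rng.exponential(20, 150)
        e = (rng.random(150) < 0.6).astype(int)
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        curve = ss.km_estimate(t, e)
        for u in curve.event_times:
            assert ss.survival_at(curve, u)[0] == pytest.approx(
                float(kmf.predict(u)), abs=1e-9)

    def test_ci_within_unit_interval_and_ordered(self, rng):
        t = rng.exponential(10, 80)
        e = (rng.random(80) < 0.8).astype(int)
        curve = ss.km_estimate(t, e)
        assert np.all(curve.ci_low >= 0) and np.all(curve.ci_high <= 1)
        assert np.all(curve.ci_low <= curve.survival + 1e-12)
        assert np.all(curve.survival <= curve.ci_high + 1e-12)
        assert np.all(np.diff(curve.survival) <= 1e-12)


class TestLogrank:
    def test_identical_groups_null_result(self):
        t = [2.0, 4.0, 6.0]
        e = [1, 0, 1]
        chi2, p = ss.logrank_test(t, e, t, e)
        assert chi2 == 0.0 and p == 1.0

    def test_against_lifelines_oracle(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        ta, tb = rng.exponential(10, 40), rng.exponential(14, 45)
        ea = (rng.random(40) < 0.8).astype(int)
        eb = (rng.random(45) < 0.8).astype(int)
        chi2, p = ss.logrank_test(ta, ea, tb, eb)
        ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_small_case_matches_permutation_oracle(self, rng):
        ta, tb = np.array([3.0, 5.0, 9.0]), np.array([2.0, 4.0, 6.0])
        ea = eb = np.ones(3, int)
        chi2_obs, _ = ss.logrank_test(ta, ea, tb, eb)
        # permutation distribution of the statistic over all 20 splits
        from itertools import combinations

        pool_t = np.concatenate([ta, tb])
        count = total = 0
        for idx in combinations(range(6), 3):
            mask = np.zeros(6, bool)
            mask[list(idx)] = True
            chi2_perm, _ = ss.logrank_test(pool_t[mask], np.ones(3, int),
                                           pool_t[~mask], np.ones(3, int))
            count += chi2_perm >= chi2_obs - 1e-12
            total += 1
        p_perm = count / total
        _, p_asym = ss.logrank_test(ta, ea, tb, eb)
        assert abs(p_asym - p_perm) < 0.25  # asymptotic vs exact, tiny n


class TestFindCutpoint:
    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError):
            ss.find_cutpoint(np.ones(20), np.arange(1, 21.0),
                             np.ones(20, int))

    def test_statistic_self_consistent_with_logrank(self, rng):
        scores = rng.uniform(0, 100, 80)
        lam = 0.02 * np.where(scores >= 50, 4.0, 1.0)
        t = rng.exponential(1 / lam)
        e = np.ones(80, int)
        cp = ss.find_cutpoint(scores, t, e)
        high = scores >= cp.threshold
        chi2, p = ss.logrank_test(t[high], e[high], t[~high], e[~high])
        assert cp.chi2 == pytest.approx(chi2)
        assert cp.p == pytest.approx(p)
        assert cp.n_high == int(high.sum())

    def test_recovers_step_hazard_threshold(self):
        rng = np.random.default_rng(5)
        scores = rng.uniform(1, 100, 300)
        lam = 0.01 * np.where(scores >= 60, 5.0, 1.0)
        t = rng.exponential(1 / lam)
        c = rng.exponential(100, 300)
        times, events = np.minimum(t, c), (t <= c).astype(int)
        cp = ss.find_cutpoint(scores, times, events)
        assert 55 <= cp.threshold <= 65

    def test_min_group_fraction_respected(self, rng):
        scores = np.concatenate([np.zeros(19), np.ones(1)])
        t = rng.exponential(10, 20)
        with pytest.raises(ValueError):
            ss.find_cutpoint(scores, t, np.ones(20, int),
                             min_group_frac=0.15)


class TestCox:
    def test_reference_recoding_inverts_hazard_ratio(self, rng):
        g = rng.integers(0, 2, 300)
        lam = 0.02 * np.exp(np.log(0.4) * g)
        t = rng.exponential(1 / lam)
        e = np.ones(300, int)
        fit_a = ss.cox_fit(pd.DataFrame({"g": g}), t, e)
        fit_b = ss.cox_fit(pd.DataFrame({"g": 1 - g}), t, e)
        assert fit_a.hr[0] == pytest.approx(1 / fit_b.hr[0], rel=1e-6)

    def test_tiny_dataset_matches_partial_likelihood_root(self):
        # n=3, no ties, no censoring: solve the score equation directly
        x = np.array([1.0, 0.0, 2.0])
        t = np.array([1.0, 2.0, 3.0])
        e = np.ones(3, int)

        def score(b):
            # events in time order: risk sets {0,1,2}, {1,2}, {2}
            s = 0.0
            for i, risk in ((0, [0, 1, 2]), (1, [1, 2]), (2, [2])):
                w = np.exp(b * x[risk])
                s += x[i] - np.sum(w * x[risk]) / np.sum(w)
            return s

        from scipy.optimize import brentq

        b_hat = brentq(score, -10, 10)
        fit = ss.cox_fit(pd.DataFrame({"x": x}), t, e)
        assert fit.coef[0] == pytest.approx(b_hat, abs=1e-5)

    def test_ties_methods_available_and_close(self, rng):
        g = rng.integers(0, 2, 100)
        t = np.maximum(np.round(rng.exponential(10, 100)), 1.0)
        e = np.ones(100, int)
        fe = ss.cox_fit(pd.DataFrame({"g": g}), t, e, ties="efron")
        fb = ss.cox_fit(pd.DataFrame({"g": g}), t, e, ties="breslow")
        assert fe.ties == "efron" and fb.ties == "breslow"
        assert fe.hr[0] == pytest.approx(fb.hr[0], rel=0.1)
        with pytest.raises(ValueError):
            ss.cox_fit(pd.DataFrame({"g": g}), t, e, ties="exact")

    def test_separation_flagged_not_raised(self):
        # group 0 all early events, group 1 all late: monotone likelihood
        g = np.array([0] * 5 + [1] * 5)
        t = np.array([1.0, 2, 3, 4, 5, 50, 60, 70, 80, 90])
        fit = ss.cox_fit(pd.DataFrame({"g": g}), t, np.ones(10, int))
        assert not fit.converged

    def test_ci_contains_hr(self, rng):
        g = rng.integers(0, 2, 200)
        t = rng.exponential(10, 200)
        fit = ss.cox_fit(pd.DataFrame({"g": g}), t, np.ones(200, int))
        assert fit.ci_low[0] <= fit.hr[0] <= fit.ci_high[0]


class TestGroupTests:
    def test_exact_mann_whitney_small_case(self):
        # all 6 rank arrangements: P(U <= 0) * 2 = 2/6
        res = ss.group_tests([1.0, 2.0, 3.0, 4.0],
                             ["a", "a", "b", "b"])
        assert res.test == "mann-whitney"
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1 / 3)

    def test_identical_samples_boundary_p(self):
        res = ss.group_tests([1.0, 2.0, 1.0, 2.0], ["a", "a", "b", "b"])
        assert res.p == pytest.approx(1.0)

    def test_kruskal_two_groups_agrees_with_mannwhitney(self, rng):
        agree = 0
        reps = 100
        for rep in range(reps):
            r = np.random.default_rng(rep)
            x = np.concatenate([r.normal(0, 1, 15), r.normal(0.8, 1, 15)])
            g = np.array(["a"] * 15 + ["b"] * 15)
            mw = ss.group_tests(x, g)
            from scipy.stats import kruskal

            _, p_kw = kruskal(x[:15], x[15:])
            agree += (mw.p < 0.05) == (p_kw < 0.05)
        assert agree >= 95

    def test_dunn_two_group_z_squared_matches_kruskal(self, rng):
        x = rng.normal(0, 1, 40)
        g = np.array(["a"] * 20 + ["b"] * 20)
        from scipy.stats import kruskal

        h, _ = kruskal(x[:20], x[20:])
        dn = ss.dunn_posthoc(x, g)
        assert dn["z"].iloc[0] ** 2 == pytest.approx(h, rel=1e-9)

    def test_three_groups_runs_kruskal_with_posthoc(self, rng):
        x = np.concatenate([rng.normal(0, 1, 20), rng.normal(0, 1, 20),
                            rng.normal(2, 1, 20)])
        g = np.repeat(["a", "b", "c"], 20)
        res = ss.group_tests(x, g)
        assert res.test == "kruskal-wallis"
        assert len(res.posthoc) == 3
        assert (res.posthoc["p_adj"] >= res.posthoc["p"] - 1e-12).all()
        sig = res.posthoc[(res.posthoc["group_a"] == "a")
                          & (res.posthoc["group_b"] == "c")]
        assert sig["p_adj"].iloc[0] < 0.05
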