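"""Variance-gated t-tests, BKY two-stage FDR, Kaplan-Meier, log-rank."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hs

from ephysepi import stats_survival as st
from ephysepi.stats_survival import SurvivalRecord


class TestCompareGroups:
    def test_identical_groups_give_t_zero(self):
        r = st.compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t_statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_closed_form_student_t(self):
        """{1,2,3} vs {4,5,6}: pooled-variance t = -3.674 on 4 df,
        two-tailed p = 0.0213."""
        r = st.compare_groups([1, 2, 3], [4, 5, 6])
        assert r.test_used == "student"
        assert r.t_statistic == pytest.approx(-3.674, abs=0.001)
        assert r.p_value == pytest.approx(0.0213, abs=0.0005)
        assert r.sem_a == pytest.approx(0.577, abs=0.001)

    def test_variance_gate_selects_welch(self):
        """Variances 1 vs 100 at n = 20/20 trip the F-test gate in
        >= 95% of 200 seeds."""
        hits = 0
        for s in range(200):
            rng = np.random.default_rng(s)
            r = st.compare_groups(rng.normal(0, 1, 20),
                                  rng.normal(0, 10, 20))
            hits += r.test_used == "welch"
        assert hits >= 190

    def test_zero_variance_in_both_groups_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            st.compare_groups([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            st.compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_normality_p_reported_for_large_groups(self):
        rng = np.random.default_rng(0)
        r = st.compare_groups(rng.normal(0, 1, 30), rng.normal(0, 1, 30))
        assert 0.0 <= r.normality_p_a <= 1.0


class TestBkyFdr:
    def test_all_high_p_rejects_nothing(self):
        assert not st.bky_fdr([0.9] * 10).any()

    def test_single_small_p_rejected(self):
        """m = 1, p = 0.01: stage 1 at q' = 0.0476 rejects, so all
        hypotheses (the one) are rejected."""
        assert st.bky_fdr([0.01]).tolist() == [True]

    def test_flags_in_input_order(self):
        flags = st.bky_fdr([0.9, 1e-6, 0.8, 1e-5])
        assert flags.tolist() == [False, True, False, True]

    def test_matches_statsmodels_reference(self):
        """Cross-check against the independent two-stage implementation
        in statsmodels on random p-value sets."""
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        for _ in range(50):
            m = int(rng.integers(3, 40))
            p = np.concatenate([rng.uniform(0, 1, m),
                                rng.uniform(0, 1e-3, int(rng.integers(0, 4)))])
            ref = multipletests(p, alpha=0.05, method="fdr_tsbky")[0]
            np.testing.assert_array_equal(st.bky_fdr(p), ref)

    def test_rejects_superset_of_bh_with_estimated_nulls(self):
        """With a sizeable fraction of clear effects the two-stage
        procedure is at least as powerful as plain Benjamini-Hochberg."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = np.concatenate([rng.uniform(0, 1, 70),
                                rng.uniform(0, 1e-4, 30)])
            bky = st.bky_fdr(p)
            m = p.size
            order = np.argsort(p)
            crit = 0.05 * np.arange(1, m + 1) / m
            hits = np.where(np.sort(p) <= crit)[0]
            bh = np.zeros(m, dtype=bool)
            if hits.size:
                bh[order[:hits[-1] + 1]] = True
            assert np.all(bky[bh])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            st.bky_fdr([])

    @pytest.mark.parametrize("n_true", [0, 50, 100])
    def test_empirical_fdr_controlled_across_null_fractions(self, n_true):
        """Empirical FDR <= q + 2 MC-SE at null fractions 1, 0.5, 0."""
        rng = np.random.default_rng(11)
        m, reps = 100, 300
        fdrs = []
        for _ in range(reps):
            p = np.concatenate([rng.uniform(0, 1e-5, n_true),
                                rng.uniform(0, 1, m - n_true)])
            flags = st.bky_fdr(p)
            r = flags.sum()
            v = flags[n_true:].sum()
            fdrs.append(v / r if r else 0.0)
        mc_se = np.std(fdrs, ddof=1) / np.sqrt(reps)
        assert np.mean(fdrs) <= 0.05 + 2 * mc_se + 1e-9


class TestKaplanMeier:
    def test_all_die_same_day(self):
        recs = [SurvivalRecord(f"s{i}", "g", 18, True) for i in range(8)]
        _, median = st.km_estimate(recs)
        assert median == 18

    def test_no_deaths_median_undefined(self):
        recs = [SurvivalRecord(f"s{i}", "g", 90, False) for i in range(8)]
        _, median = st.km_estimate(recs)
        assert median is None

    def test_hand_worked_product_limit_table(self):
        """Six subjects, one censored mid-way: S(2) = 5/6,
        S(3) = 5/6 * 3/5 = 1/2, S(5) = 1/2 * 1/2 = 1/4; median day 3."""
        recs = [
            SurvivalRecord("a", "g", 2, True),
            SurvivalRecord("b", "g", 3, True),
            SurvivalRecord("c", "g", 3, True),
            SurvivalRecord("d", "g", 4, False),
            SurvivalRecord("e", "g", 5, True),
            SurvivalRecord("f", "g", 6, False),
        ]
        curve, median = st.km_estimate(recs)
        surv = dict(zip(curve.day, curve.survival))
        assert surv[2.0] == pytest.approx(5 / 6)
        assert surv[3.0] == pytest.approx(0.5)
        assert surv[5.0] == pytest.approx(0.25)
        assert median == 3

    @given(hs.randoms(use_true_random=False))
    @settings(max_examples=10, deadline=None)
    def test_median_invariant_to_subject_order(self, rnd):
        recs = [SurvivalRecord(f"s{i}", "g", d, e) for i, (d, e) in
                enumerate([(3, True), (5, True), (7, False), (9, True),
                           (11, True), (2, True)])]
        _, m1 = st.km_estimate(recs)
        shuffled = list(recs)
        rnd.shuffle(shuffled)
        _, m2 = st.km_estimate(shuffled)
        assert m1 == m2


class TestLogrank:
    def test_identical_groups(self):
        recs = ([SurvivalRecord(f"a{i}", "a", d, True)
                 for i, d in enumerate([3, 5, 7])]
                + [SurvivalRecord(f"b{i}", "b", d, True)
                   for i, d in enumerate([3, 5, 7])])
        chi2, p = st.logrank(recs)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_non_overlapping_death_times(self):
        recs = ([SurvivalRecord(f"a{i}", "a", 18, True) for i in range(4)]
                + [SurvivalRecord(f"b{i}", "b", 25, True) for i in range(4)])
        _, p = st.logrank(recs)
        assert p < 0.01

    def test_matches_textbook_2x2_summation(self):
        """Mantel-Cox statistic equals the per-day hypergeometric
        summation oracle on a 10-subject fixture with censoring."""
        a = [(3, True), (5, True), (7, True), (9, False), (11, True)]
        b = [(4, True), (6, True), (8, False), (10, True), (12, True)]
        recs = ([SurvivalRecord(f"a{i}", "a", d, e)
                 for i, (d, e) in enumerate(a)]
                + [SurvivalRecord(f"b{i}", "b", d, e)
                   for i, (d, e) in enumerate(b)])
        chi2, _ = st.logrank(recs)

        # oracle: U = sum(d1j - n1j dj / nj), V = sum of hypergeometric
        # variances over distinct event days
        days = sorted({d for d, e in a + b if e})
        u = v = 0.0
        for day in days:
            n1 = sum(1 for d, _ in a if d >= day)
            n2 = sum(1 for d, _ in b if d >= day)
            n = n1 + n2
            d1 = sum(1 for d, e in a if d == day and e)
            d_all = d1 + sum(1 for d, e in b if d == day and e)
            u += d1 - n1 * d_all / n
            if n > 1:
                v += d_all * (n1 / n) * (1 - n1 / n) * (n - d_all) / (n - 1)
        assert chi2 == pytest.approx(u * u / v, rel=1e-6)

    def test_single_group_rejected(self):
        recs = [SurvivalRecord("a", "a", 3, True)]
        with pytest.raises(ValueError, match="2 groups"):
            st.logrank(recs)


class TestResultsTable:
    def _comparison(self, p, metric="m"):
        return st.ComparisonResult(
            metric=metric, group_a="wt", group_b="null", mean_a=1.0,
            sem_a=0.1, mean_b=2.0, sem_b=0.1, n_a=5, n_b=5,
            test_used="student", t_statistic=1.0, p_value=p, f_test_p=0.5,
            normality_p_a=0.5, normality_p_b=0.5)

    def test_stars_follow_table_legend_thresholds(self):
        assert st.significance_stars(0.03) == "*"
        assert st.significance_stars(0.007) == "**"
        assert st.significance_stars(0.002) == "***"
        assert st.significance_stars(5e-5) == "****"
        assert st.significance_stars(0.2) == ""
        assert st.significance_stars(0.002, significant=False) == ""

    def test_table_layout_and_fdr_gating(self):
        table = st.build_results_table(
            [self._comparison(1e-6, "a"), self._comparison(0.9, "b")])
        assert list(table["metric"]) == ["a", "b"]
        assert table.loc[0, "stars"] == "****"
        assert table.loc[1, "stars"] == ""
        assert table.loc[0, "q<=0.05"] and not table.loc[1, "q<=0.05"]

    def test_empty_comparisons_rejected(self):
        with pytest.raises(ValueError):
            st.build_results_table([])
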