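import numpy as np
import pytest
import scipy.stats

from fragix import (
    attach_fragility,
    build_table1,
    correlate_fi,
    kruskal_wallis,
    mann_whitney_u,
    median_iqr,
    spearman,
    summarize_cohort,
)

from _oracles import quantile_linear, spearman_rho_oracle


class TestMedianIqr:
    @pytest.mark.parametrize(
        "values, expected",
        [([1, 2, 3], (2.0, 1.5, 2.5)), ([5], (5.0, 5.0, 5.0))],
    )
    def test_interpolated_examples(self, values, expected):
        assert median_iqr(values) == pytest.approx(expected)

    def test_matches_sort_and_interpolate_oracle(self, rng):
        v = rng.gamma(2.0, 3.0, size=200)
        med, q1, q3 = median_iqr(v)
        assert med == pytest.approx(quantile_linear(v, 0.5), rel=1e-12)
        assert q1 == pytest.approx(quantile_linear(v, 0.25), rel=1e-12)
        assert q3 == pytest.approx(quantile_linear(v, 0.75), rel=1e-12)
        assert q1 <= med <= q3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_iqr([])


class TestMannWhitney:
    def test_fully_separated_small_samples_exact(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(2 / 6)

    def test_identical_multisets_give_null_u(self):
        x = [1, 2, 2, 3, 5]
        u, _ = mann_whitney_u(x, x)
        assert u == pytest.approx(len(x) ** 2 / 2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1, 2])

    def test_two_group_kruskal_agrees_asymptotically(self, rng):
        # tie-corrected, no continuity correction vs the 2-group H test
        x = rng.integers(0, 12, size=200).astype(float)
        y = rng.integers(1, 13, size=200).astype(float)
        _, p_mwu = mann_whitney_u(x, y, continuity=False)
        p_kw = float(scipy.stats.kruskal(x, y).pvalue)
        assert abs(p_mwu - p_kw) < 0.01


class TestKruskalWallis:
    def test_hand_ranked_example(self):
        h, p = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert h == pytest.approx(32 / 7, rel=1e-12)
        assert p == pytest.approx(float(scipy.stats.chi2.sf(32 / 7, df=2)), rel=1e-12)

    def test_identical_values_degenerate(self):
        assert kruskal_wallis([[2, 2], [2, 2], [2]]) == (0.0, 1.0)

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], [3, 4]])


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1, 2, 5, 9]
        assert spearman(x, [2, 4, 10, 20]).rho == pytest.approx(1.0)
        assert spearman(x, [0, -1, -2, -3]).rho == pytest.approx(-1.0)

    def test_tied_data_matches_rank_then_pearson_oracle(self, rng):
        x = rng.integers(0, 6, size=60).astype(float)
        y = x + rng.integers(0, 6, size=60)
        res = spearman(x, y)
        assert res.rho == pytest.approx(spearman_rho_oracle(x, y), abs=1e-12)
        assert res.n_pairs == 60

    def test_missing_pairs_dropped_pairwise(self):
        x = [1, 2, 3, 4, np.nan]
        y = [1, 2, 3, np.nan, 5]
        assert spearman(x, y).n_pairs == 3

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [2, 1])


class TestRankInvariance:
    def test_statistics_invariant_under_monotone_transform(self, rng):
        x = rng.gamma(2, 1, 40)
        y = rng.gamma(2, 1, 40)
        z = rng.gamma(2, 1, 40)
        f = lambda v: np.exp(v)  # strictly increasing
        assert mann_whitney_u(x, y) == pytest.approx(mann_whitney_u(f(x), f(y)))
        assert kruskal_wallis([x, y, z]) == pytest.approx(
            kruskal_wallis([f(x), f(y), f(z)])
        )
        assert spearman(x, y).rho == pytest.approx(spearman(f(x), f(y)).rho)


class TestCohortProducts:
    def test_summary_counts_and_histogram(self, small_corpus):
        df = attach_fragility(small_corpus)
        s = summarize_cohort(df)
        assert s.n_trials == len(df)
        assert sum(s.fi_histogram.values()) == s.n_trials
        assert s.n_fi_eq1 <= s.n_fi_le3 <= s.n_trials
        assert s.iqr_fi[0] <= s.median_fi <= s.iqr_fi[1]

    def test_table1_structure(self, small_corpus):
        df = attach_fragility(small_corpus)
        comparisons = {c.variable: c for c in build_table1(df)}
        assert list(comparisons) == [
            "nplfu_vs_fi", "year_bin", "multicenter", "double_blinded",
            "registered", "itt", "outcome_used", "journal_group",
        ]
        assert comparisons["journal_group"].test == "kruskal_wallis"
        assert comparisons["multicenter"].test == "mann_whitney_u"
        # group counts sum to the cohort size for every characteristic
        for comp in comparisons.values():
            assert sum(g.n for g in comp.groups) == len(df)
        # singleton journal levels report a median but no IQR
        nejm = next(g for g in comparisons["journal_group"].groups if g.label == "NEJM")
        assert nejm.n == 1 and nejm.median is not None and nejm.iqr is None

    def test_correlations_panels(self, small_corpus):
        df = attach_fragility(small_corpus)
        panels = {c.y_name: c for c in correlate_fi(df)}
        assert set(panels) == {"n_total", "total_events", "reported_p"}
        for c in panels.values():
            assert -1.0 <= c.rho <= 1.0

    def test_correlation_perfect_monotone_and_missing_p(self):
        from fragix import CorpusTable
        from conftest import make_record

        records = [
            make_record(1, 0, 10, 8, 10),
            make_record(2, 0, 30, 15, 30),
            make_record(3, 0, 80, 30, 80),
        ]
        df = attach_fragility(CorpusTable(records=records))
        assert sorted(df["fi"]) == list(df["fi"])  # FI grows with N here
        panels = {c.y_name: c for c in correlate_fi(df)}
        assert panels["n_total"].rho == pytest.approx(1.0)
        assert "reported_p" not in panels  # all reported_p missing -> panel omitted
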