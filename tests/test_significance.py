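"""Grubbs test, recursive GO-level outlier search, two-sample comparisons."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, optimize, special, stats

from exprgo import (
    DegenerateDataError,
    DomainError,
    compare_chi2,
    compare_ks,
    compute_levels,
    find_significant_terms,
    grubbs_critical,
    grubbs_test,
)

from conftest import build_graph, chain_graph, table_from_es


def t_quantile_by_integration(p, df):
    """Student-t quantile via direct pdf integration (independent of t.ppf)."""

    assert p > 0.5  # upper-tail quantiles only, which is all Grubbs needs

    def pdf(x):
        c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
        return c * (1 + x * x / df) ** (-(df + 1) / 2)

    def cdf(x):
        tail, _ = integrate.quad(pdf, 0, x, limit=200)
        return 0.5 + tail

    return optimize.brentq(lambda x: cdf(x) - p, 0.0, 500.0, xtol=1e-12)


def grubbs_critical_oracle(n, alpha):
    t = t_quantile_by_integration(1 - alpha / (2 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


class TestGrubbsCritical:
    @pytest.mark.parametrize("n", [3, 5, 10, 25])
    @pytest.mark.parametrize("alpha", [0.01, 0.05, 0.1])
    def test_matches_integration_oracle(self, n, alpha):
        assert grubbs_critical(n, alpha) == pytest.approx(
            grubbs_critical_oracle(n, alpha), abs=1e-6
        )

    def test_strictly_increasing_in_n(self):
        vals = [grubbs_critical(n, 0.05) for n in range(3, 51)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_decreasing_in_alpha(self):
        crits = [grubbs_critical(10, a) for a in (0.01, 0.05, 0.2, 0.5, 0.9)]
        assert all(b < a for a, b in zip(crits, crits[1:]))

    def test_domain_errors(self):
        with pytest.raises(DomainError, match="below 3"):
            grubbs_critical(2, 0.05)
        with pytest.raises(DomainError):
            grubbs_critical(10, 1.5)


class TestGrubbsTest:
    def test_constant_vector_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            grubbs_test([2.0, 2.0, 2.0, 2.0])

    def test_below_three_observations(self):
        with pytest.raises(DomainError):
            grubbs_test([1.0, 2.0])

    def test_planted_extreme_flagged_up(self):
        x = [0.0] * 9 + [100.0]
        records = grubbs_test(x, alpha=0.05)
        assert len(records) == 1
        rec = records[0]
        assert rec.label == "9" and rec.direction == "up"
        # statistic and threshold agree with the direct computation
        g = (100.0 - np.mean(x)) / np.std(x, ddof=1)
        assert rec.g_statistic == pytest.approx(g, rel=1e-12)
        assert rec.critical_value == pytest.approx(
            grubbs_critical_oracle(10, 0.05), abs=1e-6
        )
        assert rec.g_statistic > rec.critical_value

    def test_low_extreme_flagged_down(self):
        records = grubbs_test([5.0, 5.1, 4.9, 5.05, -50.0])
        assert [r.direction for r in records] == ["down"]

    def test_iterative_removal_finds_second_outlier(self):
        x = [0.0, 0.1, -0.1, 0.05, -0.05, 0.02, 3.0, 100.0]
        single = grubbs_test(x, alpha=0.05, iterative=False)
        assert [r.label for r in single] == ["7"]
        multi = grubbs_test(x, alpha=0.05, iterative=True)
        assert [r.label for r in multi] == ["7", "6"]
        assert [r.iteration_index for r in multi] == [0, 1]

    def test_ties_flagged_in_same_iteration(self):
        # the tied pair must be extreme enough not to mask each other
        x = [0.0] * 18 + [50.0, 50.0]
        records = grubbs_test(x, alpha=0.05)
        assert sorted(r.label for r in records) == ["18", "19"]
        assert {r.iteration_index for r in records} == {0}

    @given(
        st.lists(st.floats(-100, 100), min_size=4, max_size=30).filter(
            lambda v: np.std(v, ddof=1) > 1e-6
        ),
        st.floats(0.1, 10.0),
        st.floats(-50.0, 50.0),
    )
    def test_location_scale_invariance(self, values, a, b):
        base = grubbs_test(values, alpha=0.1)
        moved = grubbs_test([a * v + b for v in values], alpha=0.1)
        assert [r.label for r in base] == [r.label for r in moved]

    def test_type_one_error_rate_close_to_alpha(self):
        # single-pass flag rate under an i.i.d. normal null
        rng = np.random.default_rng(2024)
        n, alpha, reps = 10, 0.05, 10_000
        x = rng.standard_normal((reps, n))
        g = np.abs(x - x.mean(axis=1, keepdims=True)).max(axis=1) / x.std(
            axis=1, ddof=1
        )
        rate = float((g > grubbs_critical(n, alpha)).mean())
        se = math.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rate - alpha) < 3 * se


class TestLevelSearch:
    def _layered_setup(self, mid_f, deep_f):
        """Graph with 4 mid-level and 9 deep terms plus chosen log2 folds."""
        mid = [f"GO:{i:07d}" for i in range(2, 6)]
        deep = [f"GO:{i:07d}" for i in range(6, 15)]
        edges = [(m, "GO:0000001", "is_a") for m in mid]
        edges += [(d, mid[i % 4], "is_a") for i, d in enumerate(deep)]
        graph = build_graph(edges)
        levels = compute_levels(graph)
        # ES rows (1, 2**v) give f_avg_log == v for two samples
        rows = {t: [1.0, 2.0 ** v] for t, v in zip(mid, mid_f)}
        rows.update({t: [1.0, 2.0 ** v] for t, v in zip(deep, deep_f)})
        table = table_from_es(rows)
        return graph, levels, table

    def test_planted_term_found_at_deepest_level(self):
        graph, levels, table = self._layered_setup(
            mid_f=[0.0, 0.01, -0.01, 0.02],
            deep_f=[10.0, 0.0, 0.01, -0.01, 0.02, -0.02, 0.03, 0.0, 0.01],
        )
        report = find_significant_terms(table, graph, levels, "BP", alpha=0.05)
        assert report.level_found == 2
        assert report.levels_searched == [2]
        assert [r.label for r in report.outliers] == ["GO:0000006"]
        assert report.outliers[0].direction == "up"

    def test_no_signal_searches_down_to_level_one(self):
        graph, levels, table = self._layered_setup(
            mid_f=[0.0, 0.01, -0.01, 0.02],
            deep_f=[0.0, 0.01, -0.01, 0.02, -0.02, 0.03, -0.03, 0.01, 0.0],
        )
        report = find_significant_terms(table, graph, levels, "BP", alpha=0.05)
        assert report.level_found is None
        assert report.outliers == []
        assert report.levels_searched == [2, 1]

    def test_signal_only_at_shallower_level(self):
        graph, levels, table = self._layered_setup(
            mid_f=[0.0, 0.01, -0.01, 8.0],
            deep_f=[0.0, 0.01, -0.01, 0.02, -0.02, 0.03, -0.03, 0.01, 0.0],
        )
        report = find_significant_terms(table, graph, levels, "BP", alpha=0.05)
        assert report.levels_searched == [2, 1]
        assert report.level_found == 1
        assert [r.label for r in report.outliers] == ["GO:0000005"]

    def test_sparse_levels_are_skipped(self):
        # chain: at most 1 term per level, so every level is skipped
        graph, ids = chain_graph(3)
        rows = {t: [1.0, 2.0] for t in ids}
        table = table_from_es(rows)
        levels = compute_levels(graph)
        report = find_significant_terms(table, graph, levels, "BP")
        assert report.level_found is None
        assert report.skipped_levels == [3, 2, 1]
        assert report.n_terms_tested_per_level == {3: 1, 2: 1, 1: 1}

    def test_excluded_terms_do_not_enter_the_test(self):
        graph, levels, table = self._layered_setup(
            mid_f=[0.0, 0.01, -0.01, 0.02],
            deep_f=[10.0, 0.0, 0.01, -0.01, 0.02, -0.02, 0.03, 0.0, 0.01],
        )
        # zero out the planted term's first sample: it becomes excluded
        table.es.loc["GO:0000006", "s1"] = 0.0
        from exprgo import average_fold, stepwise_fold

        stepwise_fold(table)
        average_fold(table)
        report = find_significant_terms(table, graph, levels, "BP", alpha=0.05)
        assert all(r.label != "GO:0000006" for r in report.outliers)
        assert report.n_terms_tested_per_level[2] == 8


class TestChiSquare:
    def test_identical_samples_statistic_zero(self):
        table = table_from_es([[3, 3], [1, 1], [7, 7]])
        rep = compare_chi2(table, "s1", "s2")
        assert rep.statistic == pytest.approx(0.0)
        assert rep.p_value == pytest.approx(1.0)
        assert rep.df == 2

    def test_matches_textbook_formula(self):
        table = table_from_es([[10, 10], [10, 30]])
        rep = compare_chi2(table, "s1", "s2")
        # direct homogeneity computation on the 2x2 table
        obs = np.array([[10.0, 10.0], [10.0, 30.0]])
        row = obs.sum(axis=1, keepdims=True)
        col = obs.sum(axis=0, keepdims=True)
        expected = row * col / obs.sum()
        stat = ((obs - expected) ** 2 / expected).sum()
        assert rep.statistic == pytest.approx(stat, rel=1e-12)
        assert rep.df == 1
        assert rep.p_value == pytest.approx(stats.chi2.sf(stat, 1), rel=1e-12)

    def test_statistic_scales_with_scores(self):
        rng = np.random.default_rng(7)
        es = rng.uniform(1, 50, size=(12, 2))
        rep1 = compare_chi2(table_from_es(es), "s1", "s2")
        rep2 = compare_chi2(table_from_es(2 * es), "s1", "s2")
        assert rep2.statistic == pytest.approx(2 * rep1.statistic, rel=1e-9)

    def test_small_expected_counts_warn(self):
        table = table_from_es([[1, 2], [2, 1], [1, 1]])
        rep = compare_chi2(table, "s1", "s2")
        assert any("below 5" in w for w in rep.warnings)

    def test_too_few_bins_is_domain_error(self):
        table = table_from_es([[3, 3], [0, 0]])
        with pytest.raises(DomainError):
            compare_chi2(table, "s1", "s2")


class TestKolmogorovSmirnov:
    def test_identical_samples(self):
        table = table_from_es([[3, 3], [1, 1], [7, 7]])
        rep = compare_ks(table, "s1", "s2")
        assert rep.statistic == pytest.approx(0.0)
        assert rep.p_value == pytest.approx(1.0)

    def test_disjoint_supports_give_d_one(self):
        table = table_from_es([[1, 10], [2, 20], [3, 30]])
        rep = compare_ks(table, "s1", "s2")
        assert rep.statistic == pytest.approx(1.0)

    @given(
        st.lists(st.floats(0.01, 1e3), min_size=3, max_size=40),
        st.lists(st.floats(0.01, 1e3), min_size=3, max_size=40),
    )
    def test_d_matches_bruteforce_ecdf_sweep(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        rows = [[x, y] for x, y in zip(a, b)]
        rep = compare_ks(table_from_es(rows), "s1", "s2")
        grid = sorted(set(a) | set(b))
        d = max(
            abs(
                sum(x <= g for x in a) / len(a)
                - sum(y <= g for y in b) / len(b)
            )
            for g in grid
        )
        assert rep.statistic == pytest.approx(d, abs=1e-12)

    def test_p_value_monotone_decreasing_in_d(self):
        # same sample sizes, increasing separation
        base = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        reps = []
        for shift in (0.5, 2.0, 4.0, 10.0):
            rows = [[x, x + shift] for x in base]
            reps.append(compare_ks(table_from_es(rows), "s1", "s2"))
        ds = [r.statistic for r in reps]
        ps = [r.p_value for r in reps]
        assert all(b >= a for a, b in zip(ds, ds[1:]))
        for (d1, p1), (d2, p2) in zip(zip(ds, ps), zip(ds[1:], ps[1:])):
            if d2 > d1:
                assert p2 < p1
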