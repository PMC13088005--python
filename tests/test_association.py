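"""Chi-square tests, Monte Carlo p-values, Cramér's V, bootstrap CI, kappa."""

import math

import numpy as np
import pytest
from scipy import stats

from statrigor.association import (
    ContingencyTable,
    bootstrap_ci_cramers_v,
    chisq_gof,
    chisq_independence,
    cohens_kappa,
    cramers_v,
    effect_size_label,
    expected_counts,
    monte_carlo_pvalue,
    needs_monte_carlo,
)


class TestGoodnessOfFit:
    def test_journal_distribution_imbalance(self):
        res = chisq_gof([25, 37, 57])
        assert res.statistic == pytest.approx(13.18, abs=0.005)
        assert res.df == 2
        assert res.p_asymptotic == pytest.approx(0.001, abs=5e-4)

    def test_year_distribution_evenness(self):
        res = chisq_gof([22, 14, 18, 24, 22, 19])
        assert res.statistic == pytest.approx(3.27, abs=0.005)
        assert res.df == 5
        assert res.p_asymptotic == pytest.approx(0.659, abs=5e-4)

    def test_perfect_fit_gives_zero_statistic(self):
        res = chisq_gof([20, 20, 20, 20])
        assert res.statistic == 0.0
        assert res.p_asymptotic == pytest.approx(1.0)

    def test_nonuniform_expected_probs(self):
        res = chisq_gof([50, 50], expected_probs=[0.5, 0.5])
        assert res.statistic == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            chisq_gof([10, 10], expected_probs=[0.6, 0.5])
        with pytest.raises(ValueError):
            chisq_gof([10, 10], expected_probs=[1.0, 0.0])


class TestIndependence:
    def test_hand_computed_2x2(self):
        res = chisq_independence(ContingencyTable([[10, 5], [2, 8]]))
        assert res.statistic == pytest.approx(5.235, abs=5e-4)
        assert res.df == 1

    def test_transposition_symmetry(self):
        t = ContingencyTable([[10, 5], [2, 8]])
        tt = ContingencyTable(t.counts.T)
        assert chisq_independence(t).statistic == pytest.approx(
            chisq_independence(tt).statistic
        )

    def test_proportional_rows_give_zero(self):
        res = chisq_independence(ContingencyTable([[10, 20, 30], [1, 2, 3]]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_asymptotic == pytest.approx(1.0)

    def test_zero_margin_names_empty_level(self):
        with pytest.raises(ValueError, match="late"):
            chisq_independence(
                ContingencyTable([[5, 0], [7, 0]], col_labels=["early", "late"])
            )

    def test_agrees_with_scipy_on_random_tables(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            r, c = rng.integers(2, 5, size=2)
            counts = rng.integers(1, 30, size=(r, c))
            mine = chisq_independence(ContingencyTable(counts))
            ref = stats.chi2_contingency(counts, correction=False)
            assert mine.statistic == pytest.approx(float(ref.statistic))
            assert mine.df == int(ref.dof)

    def test_label_permutation_invariance(self):
        counts = np.array([[12, 7, 3], [4, 9, 11]])
        base = chisq_independence(ContingencyTable(counts)).statistic
        perm = chisq_independence(ContingencyTable(counts[:, [2, 0, 1]])).statistic
        assert perm == pytest.approx(base)


class TestMonteCarloTrigger:
    def test_large_expected_counts_use_asymptotic(self):
        assert not needs_monte_carlo(ContingencyTable([[20, 20], [20, 20]]))

    def test_one_third_small_cells_triggers(self):
        # margins force 3 of 9 expected counts below 5
        table = ContingencyTable([[2, 20, 20], [2, 20, 20], [2, 20, 20]])
        expected = expected_counts(table)
        assert np.sum(expected < 5) == 3
        assert needs_monte_carlo(table)

    def test_exactly_twenty_percent_is_not_triggered(self):
        table = ContingencyTable([[15, 15, 11, 6, 3], [15, 15, 11, 6, 3]])
        expected = expected_counts(table)
        assert np.sum(expected < 5) == 2  # 2 of 10 cells
        assert not needs_monte_carlo(table)


class TestMonteCarloPvalue:
    def test_zero_statistic_gives_p_one(self):
        p = monte_carlo_pvalue(ContingencyTable([[10, 20], [5, 10]]), 500, seed=0)
        assert p == 1.0

    def test_add_one_bounds_and_determinism(self):
        table = ContingencyTable([[10, 0], [0, 10]])
        p1 = monte_carlo_pvalue(table, 999, seed=4)
        p2 = monte_carlo_pvalue(table, 999, seed=4)
        assert p1 == p2
        assert 1 / 1000 <= p1 <= 1.0

    def test_matches_asymptotic_for_well_filled_table(self):
        table = ContingencyTable([[40, 30, 25], [30, 35, 30], [25, 30, 40]])
        asym = chisq_independence(table).p_asymptotic
        replicates = 20_000
        p_mc = monte_carlo_pvalue(table, replicates, seed=8)
        se = math.sqrt(asym * (1 - asym) / replicates)
        assert abs(p_mc - asym) < 3 * se


class TestCramersV:
    def test_extremes(self):
        assert cramers_v(ContingencyTable([[10, 0], [0, 10]])) == pytest.approx(1.0)
        assert cramers_v(ContingencyTable([[5, 5], [5, 5]])) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        assert cramers_v(ContingencyTable([[10, 5], [2, 8]])) == pytest.approx(
            math.sqrt(5.235042735042735 / 25), abs=1e-9
        )

    def test_agrees_with_independent_formula_on_random_tables(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            r, c = rng.integers(2, 5, size=2)
            counts = rng.integers(1, 25, size=(r, c))
            table = ContingencyTable(counts)
            chi2 = float(stats.chi2_contingency(counts, correction=False).statistic)
            expected = math.sqrt(chi2 / (counts.sum() * (min(r, c) - 1)))
            assert cramers_v(table) == pytest.approx(expected)
            assert 0.0 <= cramers_v(table) <= 1.0


class TestBootstrapCI:
    @staticmethod
    def correlated_pairs(n, seed, flip=0.25):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, n)
        y = np.where(rng.random(n) < 1 - flip, x, rng.integers(0, 2, n))
        return x, y

    def test_same_seed_gives_identical_interval(self):
        x, y = self.correlated_pairs(200, 3)
        a = bootstrap_ci_cramers_v(x, y, replicates=200, seed=12)
        b = bootstrap_ci_cramers_v(x, y, replicates=200, seed=12)
        assert a == b

    def test_interval_is_ordered_and_within_unit_range(self):
        x, y = self.correlated_pairs(100, 5)
        lo, hi = bootstrap_ci_cramers_v(x, y, replicates=300, seed=1)
        assert 0.0 <= lo <= hi <= 1.0

    def test_interval_covers_point_estimate_at_moderate_n(self):
        # association built to give V around 0.5
        for seed in range(5):
            x, y = self.correlated_pairs(500, 100 + seed, flip=0.5)
            v = cramers_v(ContingencyTable.from_pairs(x, y))
            lo, hi = bootstrap_ci_cramers_v(x, y, replicates=500, seed=seed)
            assert lo <= v <= hi

    def test_interval_width_shrinks_with_sample_size(self):
        widths = {n: [] for n in (100, 1000)}
        for n in widths:
            for seed in range(10):
                x, y = self.correlated_pairs(n, 200 + seed, flip=0.5)
                lo, hi = bootstrap_ci_cramers_v(x, y, replicates=200, seed=seed)
                widths[n].append(hi - lo)
        assert np.median(widths[1000]) < np.median(widths[100])

    def test_collapse_policy_zero_scores_degenerate_resamples(self):
        # tiny sample with a rare level: collapses are common
        x = ["a"] * 9 + ["b"]
        y = ["u"] * 9 + ["v"]
        lo_zero, _ = bootstrap_ci_cramers_v(x, y, replicates=300, seed=2, collapse="zero")
        assert lo_zero == 0.0

    def test_single_level_axis_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci_cramers_v(["a"] * 10, list("uvuvuvuvuv"), replicates=10, seed=0)


class TestEffectSizeLabel:
    @pytest.mark.parametrize(
        "v,label",
        [
            (0.085, "negligible"),
            (0.183, "small"),
            (0.873, "large"),
            (0.1, "small"),
            (0.3, "medium"),
            (0.5, "large"),
            (0.0, "negligible"),
            (1.0, "large"),
        ],
    )
    def test_cohen_bins_left_closed(self, v, label):
        assert effect_size_label(v) == label


class TestCohensKappa:
    def test_perfect_agreement(self):
        assert cohens_kappa(list("abcabc"), list("abcabc")) == pytest.approx(1.0)

    def test_hand_computed_cross_table(self):
        # agreement table [[20, 5], [10, 15]]: p_o = 0.7, p_e = 0.5
        a = ["x"] * 25 + ["y"] * 25
        b = ["x"] * 20 + ["y"] * 5 + ["x"] * 10 + ["y"] * 15
        assert cohens_kappa(a, b) == pytest.approx(0.4)

    def test_chance_level_agreement_is_zero(self):
        assert cohens_kappa(["x", "x", "y", "y"], ["x", "y", "x", "y"]) == pytest.approx(0.0)

    def test_agrees_with_sklearn_on_random_ratings(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(31)
        for _ in range(20):
            n = int(rng.integers(10, 60))
            a = rng.integers(0, 3, n).astype(str)
            b = rng.integers(0, 3, n).astype(str)
            assert cohens_kappa(a, b) == pytest.approx(
                cohen_kappa_score(a, b), abs=1e-12
            )

    def test_degenerate_constant_raters_reported_as_nan(self):
        assert math.isnan(cohens_kappa(["a", "a", "a"], ["a", "a", "a"]))
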