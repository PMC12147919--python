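import numpy as np
import pytest
from scipy import stats

from orievolve.association_stats import (
    compact_letter_display,
    fisher_2x2,
    interface_enrichment,
    pearson_bh,
    regress,
    tukey_hsd,
    welch_satterthwaite_df,
    welch_t,
)

from _oracles import fisher_two_sided


class TestRegress:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = regress(x, 2 * x + 1)
        assert fit.adjusted_r_squared == pytest.approx(1.0)
        assert fit.coefficients[0] == pytest.approx(1.0)
        assert fit.coefficients[1] == pytest.approx(2.0)

    def test_coefficients_match_normal_equations(self):
        """5-point quadratic toy against the closed-form OLS solution."""
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([1.1, 0.9, 2.3, 4.8, 9.1])
        design = np.vander(x, 3, increasing=True)
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        fit = regress(x, y, degree=2)
        assert np.allclose(fit.coefficients, beta)

    def test_null_p_values_are_calibrated(self, rng):
        hits = 0
        n_sims = 200
        for _ in range(n_sims):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            if regress(x, y).p_value < 0.05:
                hits += 1
        se = np.sqrt(0.05 * 0.95 / n_sims)
        assert hits / n_sims < 0.05 + 4 * se

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            regress(np.ones(10), np.arange(10.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            regress(np.array([1.0, 2.0]), np.array([1.0, 2.0]), degree=1)

    def test_adjusted_r2_below_r2(self, rng):
        x = rng.normal(size=15)
        y = 0.3 * x + rng.normal(size=15)
        fit = regress(x, y)
        assert fit.adjusted_r_squared <= fit.r_squared <= 1.0


class TestTukey:
    def test_identical_groups_share_letter(self, rng):
        base = list(rng.normal(1.0, 0.2, size=6))
        result = tukey_hsd({"a": base, "b": base})
        assert result.letters["a"] == result.letters["b"]
        assert result.p_values.loc["a", "b"] == pytest.approx(1.0)

    def test_separated_groups_distinct_letters(self, rng):
        result = tukey_hsd(
            {
                "low": rng.normal(0.0, 0.01, size=5),
                "high": rng.normal(10.0, 0.01, size=5),
            }
        )
        assert set(result.letters["low"]) & set(result.letters["high"]) == set()

    def test_two_groups_match_student_t(self, rng):
        """With k=2 the studentized range collapses to the pooled t test."""
        x = rng.normal(0.0, 1.0, size=6)
        y = rng.normal(0.8, 1.0, size=6)
        result = tukey_hsd({"x": list(x), "y": list(y)})
        _, p_t = stats.ttest_ind(x, y, equal_var=True)
        assert result.p_values.loc["x", "y"] == pytest.approx(p_t, rel=1e-6)

    def test_letter_display_on_three_tiers(self, rng):
        result = tukey_hsd(
            {
                "low": rng.normal(0.0, 0.05, size=6),
                "mid": rng.normal(1.0, 0.05, size=6),
                "high": rng.normal(2.0, 0.05, size=6),
            }
        )
        letters = result.letters
        assert len({letters["low"], letters["mid"], letters["high"]}) == 3

    def test_requires_replicates(self):
        with pytest.raises(ValueError):
            tukey_hsd({"a": [1.0], "b": [1.0, 2.0]})


class TestCompactLetterDisplay:
    def test_no_differences_single_letter(self):
        letters = compact_letter_display(
            ["a", "b", "c"], {"a": 3.0, "b": 2.0, "c": 1.0}, set()
        )
        assert set(letters.values()) == {"a"}

    def test_chain_structure(self):
        # a ~ b, b ~ c but a != c: b must share letters with both
        letters = compact_letter_display(
            ["a", "b", "c"], {"a": 3.0, "b": 2.0, "c": 1.0}, {("a", "c")}
        )
        assert set(letters["a"]) & set(letters["b"])
        assert set(letters["b"]) & set(letters["c"])
        assert not set(letters["a"]) & set(letters["c"])

    def test_every_group_lettered(self):
        significant = {("a", "b"), ("a", "c"), ("a", "d")}
        letters = compact_letter_display(
            ["a", "b", "c", "d"],
            {"a": 5.0, "b": 1.0, "c": 0.9, "d": 0.8},
            significant,
        )
        assert all(letters[g] for g in "abcd")


class TestFisher2x2:
    def test_proportional_table(self):
        p, odds = fisher_2x2(10, 20, 30, 60)
        assert p == pytest.approx(1.0)
        assert odds == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        p, _ = fisher_2x2(12, 5, 29, 2)
        assert p == pytest.approx(fisher_two_sided(12, 5, 29, 2), rel=1e-9)

    def test_zero_margin_convention(self):
        p, _ = fisher_2x2(0, 0, 5, 7)
        assert p == 1.0

    def test_symmetry_under_double_swap(self, rng):
        for _ in range(20):
            a, b, c, d = (int(v) for v in rng.integers(0, 30, size=4))
            if (a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0):
                continue
            p1, _ = fisher_2x2(a, b, c, d)
            p2, _ = fisher_2x2(d, c, b, a)
            assert p1 == pytest.approx(p2, rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_2x2(-1, 2, 3, 4)


class TestWelch:
    def test_identical_samples_p_one(self):
        t, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_df_matches_hand_formula(self, rng):
        x = rng.normal(0, 1, size=3)
        y = rng.normal(0, 3, size=5)
        vx, vy = x.var(ddof=1) / 3, y.var(ddof=1) / 5
        df_hand = (vx + vy) ** 2 / (vx**2 / 2 + vy**2 / 4)
        assert welch_satterthwaite_df(x, y) == pytest.approx(df_hand)
        # and scipy's p corresponds to that df
        t, p = welch_t(x, y)
        p_hand = 2 * stats.t.sf(abs(t), df_hand)
        assert p == pytest.approx(p_hand, rel=1e-9)

    def test_affine_invariance(self, rng):
        x = rng.normal(1.0, 0.5, size=6)
        y = rng.normal(1.4, 0.8, size=7)
        t1, p1 = welch_t(x, y)
        t2, p2 = welch_t(3 * x + 10, 3 * y + 10)
        assert t1 == pytest.approx(t2)
        assert p1 == pytest.approx(p2)


class TestPearsonBH:
    def test_perfect_linear(self):
        frame = pearson_bh({"p": ([1, 2, 3, 4], [2, 4, 6, 8])})
        assert frame.r.iloc[0] == pytest.approx(1.0)

    def test_antisymmetry(self):
        x = [0.3, 1.2, 2.2, 4.0, 5.5]
        frame = pearson_bh({"p": (x, [-v for v in x])})
        assert frame.r.iloc[0] == pytest.approx(-1.0)

    def test_r_matches_hand_formula(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        r_hand = np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
        frame = pearson_bh({"p": (x, y)})
        assert frame.r.iloc[0] == pytest.approx(r_hand, rel=1e-9)

    def test_zero_variance_flagged(self):
        frame = pearson_bh({"p": ([1, 1, 1], [1, 2, 3])})
        assert np.isnan(frame.r.iloc[0])
        assert np.isnan(frame.q_value.iloc[0])

    def test_bh_across_pairs(self, rng):
        pairs = {
            f"pair{i}": (rng.normal(size=10), rng.normal(size=10))
            for i in range(5)
        }
        frame = pearson_bh(pairs)
        assert (frame.q_value >= frame.p_value - 1e-12).all()


class TestInterfaceEnrichment:
    def test_all_candidates_on_interface(self):
        candidates = set(range(1, 21))
        interface = set(range(1, 31))
        p, odds = interface_enrichment(candidates, interface, 300)
        expected = fisher_two_sided(20, 0, 10, 270)
        assert p == pytest.approx(expected, rel=1e-9)
        assert p < 1e-10

    def test_interface_covering_everything_p_one(self):
        p, _ = interface_enrichment({1, 5, 9}, set(range(1, 101)), 100)
        assert p == 1.0

    def test_proportional_sampling_near_unit_odds(self, rng):
        interface = set(range(1, 101))  # 1/3 of residues
        candidates = set(
            int(r) for r in rng.choice(np.arange(1, 301), size=60, replace=False)
        )
        p, odds = interface_enrichment(candidates, interface, 300)
        assert p > 0.001  # no systematic enrichment signal

    def test_empty_interface_rejected(self):
        with pytest.raises(ValueError):
            interface_enrichment({1}, set(), 100)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            interface_enrichment({500}, {1, 2}, 100)
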