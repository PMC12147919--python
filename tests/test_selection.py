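import numpy as np
import pytest

from orievolve.population import ClonePopulation, PhenotypeMap
from orievolve.reference import WILD_TYPE, MutantGenotype
from orievolve.simulate.eppcr import assign_phenotypes, mutagenize_library
from orievolve.simulate.selection import (
    CheckerboardGrowthParams,
    SelectionCondition,
    SelectionModel,
    apply_selection,
    build_checkerboard,
    expected_frequencies,
    select_conditions,
    simulate_checkerboard,
)

from _oracles import expected_selected_frequency


def two_clone_setup(ori, copies_mutant=47.5):
    pos = ori.orf_start + 4
    alt = "A" if ori.amplicon[pos] != "A" else "G"
    mutant = MutantGenotype((ori.substitution(pos, alt),))
    pop = ClonePopulation(ori, {WILD_TYPE: 900, mutant: 100})
    phen = PhenotypeMap(
        ori,
        copy_number={WILD_TYPE: ori.wt_copy_number, mutant: copies_mutant},
    )
    return pop, phen, mutant


class TestSelectionModel:
    def test_weight_is_one_without_gentamicin(self):
        model = SelectionModel()
        w = model.weight(0.0, np.array([1.0, 10.0, 100.0]), 5e-6)
        assert np.all(w == 1.0)

    def test_weight_monotone_in_copies(self):
        model = SelectionModel()
        copies = np.array([1.0, 5.0, 20.0, 100.0])
        w = model.weight(750.0, copies, 5e-6)
        assert np.all(np.diff(w) > 0)
        assert np.all((w > 0) & (w <= 1))

    def test_weight_decreasing_in_gentamicin(self):
        model = SelectionModel()
        w = [model.weight(g, 9.5, 5e-6) for g in (0, 100, 500, 2000)]
        assert all(b < a for a, b in zip(w, w[1:]))

    def test_induction_range(self):
        model = SelectionModel()
        assert model.induction(0.0) == model.i_min
        assert model.induction(1.0) == pytest.approx(model.i_max, rel=1e-5)


class TestApplySelection:
    def test_no_gentamicin_preserves_expected_frequencies(self, small_ori):
        pop, phen, mutant = two_clone_setup(small_ori)
        condition = SelectionCondition(0.0, 5e-6)
        freqs = expected_frequencies(pop, phen, condition, SelectionModel())
        assert freqs[mutant] == pytest.approx(0.1)
        assert freqs[WILD_TYPE] == pytest.approx(0.9)

    def test_uniform_copy_numbers_preserve_frequencies(self, small_ori):
        pop, phen, mutant = two_clone_setup(
            small_ori, copies_mutant=small_ori.wt_copy_number
        )
        condition = SelectionCondition(750.0, 5e-6)
        freqs = expected_frequencies(pop, phen, condition, SelectionModel())
        assert freqs[mutant] == pytest.approx(0.1)

    def test_output_total_is_exact(self, small_ori):
        pop, phen, _ = two_clone_setup(small_ori)
        out = apply_selection(
            pop, phen, SelectionCondition(750.0, 5e-6), SelectionModel(),
            seed=3, output_total=12_345,
        )
        assert out.total == 12_345

    def test_resampled_frequency_matches_closed_form(self, small_ori):
        """Causal-allele frequency after selection tracks the weight arithmetic."""
        pop, phen, mutant = two_clone_setup(small_ori)
        model = SelectionModel()
        condition = SelectionCondition(750.0, 5e-6)
        w = model.weight(
            condition.gentamicin,
            np.array([small_ori.wt_copy_number, 47.5]),
            condition.salicylic_acid,
        )
        expected = expected_selected_frequency(
            [0.9, 0.1], w, model.generations
        )[1]
        n_out = 50_000
        out = apply_selection(
            pop, phen, condition, model, seed=8, output_total=n_out
        )
        observed = out.frequency_of(mutant)
        se = np.sqrt(expected * (1 - expected) / n_out)
        assert abs(observed - expected) < 3 * se

    def test_extinct_population_returned_not_raised(self, small_ori):
        pop, phen, _ = two_clone_setup(small_ori, copies_mutant=9.5)
        # degenerate dose: every growth weight underflows to exactly zero
        model = SelectionModel(i_min=1e-12, beta=8.0)
        condition = SelectionCondition(1e300, 0.0)
        out = apply_selection(pop, phen, condition, model, seed=1)
        assert out.extinct
        assert out.total == 0

    def test_missing_phenotype_rejected(self, small_ori):
        pop, _, _ = two_clone_setup(small_ori)
        phen = PhenotypeMap(small_ori, {WILD_TYPE: small_ori.wt_copy_number})
        with pytest.raises(ValueError, match="phenotype"):
            apply_selection(pop, phen, SelectionCondition(10, 1e-6))

    def test_neutral_selection_frequency_drift_is_unbiased(self, small_ori):
        """With uniform copies, allele-frequency changes average to ~zero."""
        pop, phen, mutant = two_clone_setup(
            small_ori, copies_mutant=small_ori.wt_copy_number
        )
        condition = SelectionCondition(750.0, 5e-6)
        deltas = []
        for seed in range(40):
            out = apply_selection(
                pop, phen, condition, SelectionModel(), seed=seed,
                output_total=10_000,
            )
            deltas.append(out.frequency_of(mutant) - 0.1)
        mean_delta = np.mean(deltas)
        se = np.sqrt(0.1 * 0.9 / 10_000 / len(deltas))
        assert abs(mean_delta) < 4 * se


class TestMonotonicity:
    def test_causal_frequency_monotone_in_gentamicin(self, small_ori, rng):
        """Expected causal-allele frequency never drops as gentamicin rises."""
        grid = build_checkerboard()
        pop, phen, mutant = two_clone_setup(small_ori)
        for _ in range(20):
            model = SelectionModel(
                i_min=float(rng.uniform(0.001, 0.1)),
                k_s=float(rng.uniform(0.05e-6, 1e-6)),
                hill=float(rng.uniform(0.5, 3.0)),
                alpha=float(rng.uniform(5.0, 50.0)),
                beta=float(rng.uniform(0.5, 4.0)),
                generations=int(rng.integers(1, 15)),
            )
            sa = grid.salicylic_acid(11)
            freqs = []
            for row in range(grid.n_rows):
                condition = SelectionCondition(grid.gentamicin(row), sa)
                f = expected_frequencies(pop, phen, condition, model)
                freqs.append(f[mutant] if f else 1.0)
            # rows run from high to low gentamicin: frequency must not rise
            assert all(
                b <= a + 1e-12 for a, b in zip(freqs, freqs[1:])
            ), freqs


class TestCheckerboard:
    def test_printed_endpoint_concentrations(self):
        grid = build_checkerboard()
        top = grid.condition(0, 11)
        assert top.gentamicin == pytest.approx(3000.0)
        assert top.salicylic_acid == pytest.approx(5e-6)
        assert grid.gentamicin(7) == pytest.approx(3000.0 / 2**7)  # 23.4 mg/L
        assert grid.gentamicin(7) == pytest.approx(23.4, abs=0.05)
        assert grid.salicylic_acid(0) == pytest.approx(5e-6 / 2**11)
        assert grid.salicylic_acid(0) == pytest.approx(2.44e-9, abs=0.005e-9)

    def test_grid_has_96_conditions(self):
        grid = build_checkerboard()
        conditions = grid.conditions()
        assert len(conditions) == 96
        assert conditions[0].well == "A1"
        assert conditions[-1].well == "H12"

    def test_rejects_nonpositive_start(self):
        with pytest.raises(ValueError):
            build_checkerboard(gent_start=0.0)

    def test_select_conditions_trivial_cases(self):
        grid = build_checkerboard()
        od = np.full((8, 12), 0.5)
        assert select_conditions(grid, od, od.copy(), 0.2) == []
        low = np.full((8, 12), 0.01)
        high = np.full((8, 12), 0.9)
        assert len(select_conditions(grid, low, high, 0.2)) == 96
        with pytest.raises(ValueError):
            select_conditions(grid, low, high, 0.0)

    def test_checkerboard_isolates_wt_lethal_conditions(self, small_ori):
        """A x5-copy clone at 10% opens conditions concentrated at high drug."""
        pop, phen, mutant = two_clone_setup(small_ori)
        wt_pop = ClonePopulation.wild_type_only(small_ori, 1000)
        wt_phen = PhenotypeMap(
            small_ori, {WILD_TYPE: small_ori.wt_copy_number}
        )
        model = SelectionModel()
        grid = build_checkerboard()
        od_wt, od_mut = simulate_checkerboard(
            wt_pop, pop, wt_phen, phen, model, grid,
            CheckerboardGrowthParams(), seed=0,
        )
        selected = select_conditions(grid, od_wt, od_mut, 0.2)
        assert selected, "expected a non-empty purple set"
        # purple wells sit strictly above the WT-survivable gentamicin range
        # within each inducer column
        for cond in selected:
            wt_ok = [
                grid.gentamicin(r)
                for r in range(grid.n_rows)
                if od_wt[r, cond.col] >= 0.2
            ]
            if wt_ok:
                assert cond.gentamicin > max(wt_ok)
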