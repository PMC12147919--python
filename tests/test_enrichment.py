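import numpy as np
import pandas as pd
import pytest

import orievolve.enrichment as enr
from orievolve.variant_counts import PositionCounts

from _oracles import bh_step_up, fisher_two_sided


def make_counts(ori, fill=None):
    counts = np.zeros((len(ori), 6), dtype=np.int64)
    if fill is not None:
        for pos, base_code, value in fill:
            counts[pos, base_code] = value
    return PositionCounts("s", ori.name, counts, n_reads_mapped=1)


def base_code(b):
    return "ACGT".index(b)


class TestAlleleFrequencies:
    def test_frequency_arithmetic(self, small_ori):
        pos = 5
        ref = small_ori.amplicon[pos]
        alt = "G" if ref != "G" else "A"
        counts = make_counts(
            small_ori,
            [(pos, base_code(ref), 990), (pos, base_code(alt), 10)],
        )
        table = enr.allele_frequencies(counts, small_ori, min_depth=100)
        row = table[(table.position == pos) & (table.alt == alt)].iloc[0]
        assert row.frequency == pytest.approx(0.01)
        assert row.depth == 1000
        assert not row.low_depth

    def test_three_alt_rows_per_position(self, small_ori):
        counts = make_counts(small_ori)
        table = enr.allele_frequencies(counts, small_ori)
        assert len(table) == 3 * len(small_ori)
        assert (table.ref != table.alt).all()
        assert (table.frequency == 0).all()
        assert table.low_depth.all()

    def test_masked_excluded_from_depth(self, small_ori):
        pos = 7
        ref = small_ori.amplicon[pos]
        counts = make_counts(small_ori, [(pos, base_code(ref), 200), (pos, 4, 800)])
        table = enr.allele_frequencies(counts, small_ori)
        assert (table[table.position == pos].depth == 200).all()


class TestFoldChanges:
    def test_identical_tables_give_unit_fold_change(self, small_ori):
        counts = make_counts(small_ori, [(3, base_code(small_ori.amplicon[3]), 500)])
        table = enr.allele_frequencies(counts, small_ori)
        records = enr.fold_changes(table, table)
        assert np.allclose(records.fold_change, 1.0)

    def test_headline_arithmetic(self):
        """40/2000 vs 2/2000 with pseudocount 0.5 -> 16.2-fold."""
        sel = pd.DataFrame(
            {"position": [0], "ref": ["A"], "alt": ["G"], "alt_count": [40],
             "depth": [2000], "frequency": [0.02], "low_depth": [False]}
        )
        unsel = sel.assign(alt_count=[2], frequency=[0.001])
        records = enr.fold_changes(sel, unsel)
        assert records.fold_change.iloc[0] == pytest.approx(40.5 / 2.5)

    def test_swap_gives_exact_reciprocal(self, small_ori, rng):
        counts_a = make_counts(
            small_ori,
            [(p, b, int(v)) for p, b, v in zip(
                rng.integers(0, len(small_ori), 50),
                rng.integers(0, 4, 50),
                rng.integers(1, 500, 50),
            )],
        )
        counts_b = make_counts(
            small_ori,
            [(p, b, int(v)) for p, b, v in zip(
                rng.integers(0, len(small_ori), 50),
                rng.integers(0, 4, 50),
                rng.integers(1, 500, 50),
            )],
        )
        ta = enr.allele_frequencies(counts_a, small_ori)
        tb = enr.allele_frequencies(counts_b, small_ori)
        forward = enr.fold_changes(ta, tb).fold_change.to_numpy()
        backward = enr.fold_changes(tb, ta).fold_change.to_numpy()
        assert np.allclose(forward * backward, 1.0, rtol=1e-12)

    def test_depth_invariance_bound(self, small_ori):
        """Doubling all counts moves any fold change by < 1%."""
        pos = 9
        ref = small_ori.amplicon[pos]
        alt = "C" if ref != "C" else "T"
        def table(scale):
            counts = make_counts(
                small_ori,
                [(pos, base_code(ref), 900 * scale),
                 (pos, base_code(alt), 100 * scale)],
            )
            return enr.allele_frequencies(counts, small_ori)
        f1 = enr.fold_changes(table(1), table(1))
        f2 = enr.fold_changes(table(2), table(2))
        sub = f1.depth_sel > 0
        ratio = f2.fold_change[sub] / f1.fold_change[sub]
        assert np.all(np.abs(ratio - 1) < 0.01)


class TestEnrichmentTest:
    def test_identical_tables_p_one(self):
        records = pd.DataFrame(
            {"alt_sel": [10], "depth_sel": [1000], "alt_unsel": [10],
             "depth_unsel": [1000]}
        )
        out = enr.enrichment_test(records)
        assert out.p_value.iloc[0] == pytest.approx(1.0)
        assert out.q_value.iloc[0] >= out.p_value.iloc[0]

    def test_p_matches_hypergeometric_enumeration(self):
        """[[50, 950], [1, 999]] against the brute-force tail sum."""
        records = pd.DataFrame(
            {"alt_sel": [50], "depth_sel": [1000], "alt_unsel": [1],
             "depth_unsel": [1000]}
        )
        out = enr.enrichment_test(records)
        expected = fisher_two_sided(50, 950, 1, 999)
        assert out.p_value.iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_degenerate_margin_p_one(self):
        records = pd.DataFrame(
            {"alt_sel": [0], "depth_sel": [1000], "alt_unsel": [0],
             "depth_unsel": [1000]}
        )
        assert enr.enrichment_test(records).p_value.iloc[0] == 1.0

    def test_batch_fisher_matches_scipy(self, rng):
        """Vectorized exact test agrees with scipy on random tables."""
        from scipy.stats import fisher_exact

        tables = rng.integers(0, 120, size=(60, 4))
        p_batch = enr.fisher_exact_batch(*tables.T)
        for row, p in zip(tables, p_batch):
            a, b, c, d = (int(v) for v in row)
            if min(a + b, c + d, a + c, b + d) == 0:
                assert p == 1.0
                continue
            expected = fisher_exact([[a, b], [c, d]])[1]
            assert p == pytest.approx(expected, rel=1e-8, abs=1e-12)

    def test_bh_step_up_hand_example(self):
        """q for p = (.01,.02,.03,.04), m=4 is (.04,.04,.04,.04)."""
        records = pd.DataFrame(
            {"alt_sel": [0, 0, 0, 0], "depth_sel": [1] * 4,
             "alt_unsel": [0] * 4, "depth_unsel": [1] * 4}
        )
        out = enr.enrichment_test(records)
        p = np.array([0.01, 0.02, 0.03, 0.04])
        out["p_value"] = p
        from statsmodels.stats.multitest import multipletests

        q = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
        assert np.allclose(q, bh_step_up(p))


class TestAnnotateCodons:
    @pytest.fixture()
    def records_at(self, small_ori):
        def build(position, alt):
            return pd.DataFrame(
                {"position": [position], "ref": [small_ori.amplicon[position]],
                 "alt": [alt], "alt_sel": [1], "depth_sel": [10],
                 "alt_unsel": [1], "depth_unsel": [10], "f_sel": [0.1],
                 "f_unsel": [0.1], "fold_change": [1.0], "low_depth": [False]}
            )
        return build

    def test_first_orf_position_is_codon_one(self, small_ori, records_at):
        pos = small_ori.orf_start  # the A of ATG
        out = enr.annotate_codons(records_at(pos, "G"), small_ori)
        assert out.codon_index.iloc[0] == 1

    def test_start_codon_atg_to_ata_nonsynonymous(self, small_ori, records_at):
        pos = small_ori.orf_start + 2  # ATG -> ATA is M -> I
        assert small_ori.codon(1) == "ATG"
        out = enr.annotate_codons(records_at(pos, "A"), small_ori)
        assert out.aa_ref.iloc[0] == "M"
        assert out.aa_alt.iloc[0] == "I"
        assert bool(out.nonsynonymous.iloc[0])

    def test_synonymous_leucine(self, small_ori, records_at):
        # find a CTG codon or build the records directly on any codon whose
        # wobble change is synonymous
        for residue in range(2, small_ori.n_residues):
            codon = small_ori.codon(residue)
            from orievolve.reference import translate

            wobble = small_ori.orf_start + 3 * (residue - 1) + 2
            for alt in "ACGT":
                if alt == codon[2]:
                    continue
                if translate(codon[:2] + alt) == translate(codon):
                    out = enr.annotate_codons(records_at(wobble, alt), small_ori)
                    assert not bool(out.nonsynonymous.iloc[0])
                    return
        pytest.skip("no synonymous wobble change in this reference")

    def test_flank_positions_unannotated(self, small_ori, records_at):
        out = enr.annotate_codons(records_at(0, "G" if small_ori.amplicon[0] != "G" else "C"), small_ori)
        assert pd.isna(out.codon_index.iloc[0])
        assert pd.isna(out.nonsynonymous.iloc[0])


class TestResidueAggregation:
    def make_records(self, rows):
        return pd.DataFrame(
            rows,
            columns=["position", "alt", "fold_change", "codon_index",
                     "aa_ref", "aa_alt", "nonsynonymous", "low_depth",
                     "q_value"],
        )

    def test_max_rule(self):
        records = self.make_records(
            [
                (10, "A", 1.2, 4, "L", "P", True, False, 0.5),
                (11, "C", 7.0, 4, "L", "R", True, False, 0.01),
                (12, "G", 0.4, 4, "L", "H", True, False, 0.9),
            ]
        )
        out = enr.aggregate_residues(records)
        assert len(out) == 1
        assert out.fold_change.iloc[0] == 7.0
        assert out.best_position.iloc[0] == 11
        assert out.min_q.iloc[0] == 0.01

    def test_synonymous_only_residue_absent(self):
        records = self.make_records(
            [(10, "A", 9.0, 4, "L", "L", False, False, 0.5)]
        )
        assert enr.aggregate_residues(records).empty

    def test_low_depth_excluded(self):
        records = self.make_records(
            [(10, "A", 9.0, 4, "L", "P", True, True, 0.5),
             (13, "A", 2.0, 5, "K", "R", True, False, 0.5)]
        )
        out = enr.aggregate_residues(records)
        assert out.residue_index.tolist() == [5]

    def test_matches_groupby_oracle(self, rng):
        rows = []
        for i in range(200):
            rows.append(
                (i, "ACGT"[i % 4], float(rng.uniform(0.1, 30)),
                 int(rng.integers(1, 11)), "L", "P",
                 bool(rng.random() < 0.8), bool(rng.random() < 0.1),
                 float(rng.uniform(0, 1)))
            )
        records = self.make_records(rows)
        out = enr.aggregate_residues(records)
        usable = records[records.nonsynonymous & ~records.low_depth]
        expected = usable.groupby("codon_index").fold_change.max()
        got = out.set_index("residue_index").fold_change
        assert got.to_dict() == expected.to_dict()


class TestTopResidues:
    def frame(self, items):
        return pd.DataFrame(
            [{"residue_index": r, "fold_change": fc} for r, fc in items]
        )

    def test_three_largest(self):
        result = enr.top_residues(
            self.frame([(1, 5.0), (2, 9.0), (3, 1.0), (4, 7.0)]), k=3
        )
        assert result.residues.residue_index.tolist() == [2, 4, 1]
        assert result.threshold == 5.0
        assert result.shortfall == 0

    def test_tie_at_boundary_prefers_lower_residue(self):
        result = enr.top_residues(
            self.frame([(9, 5.0), (2, 5.0), (7, 9.0)]), k=2
        )
        assert result.residues.residue_index.tolist() == [7, 2]

    def test_shortfall_reported(self):
        result = enr.top_residues(self.frame([(1, 2.0)]), k=20)
        assert result.shortfall == 19
        assert len(result.residues) == 1

    def test_matches_sort_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 40))
            items = [
                (int(r), float(np.round(rng.uniform(0, 5), 1)))
                for r in rng.choice(1000, size=n, replace=False)
            ]
            k = int(rng.integers(1, 25))
            result = enr.top_residues(self.frame(items), k=k)
            expected = sorted(items, key=lambda t: (-t[1], t[0]))[:k]
            assert result.residues.residue_index.tolist() == [r for r, _ in expected]


class TestRecoveryMetrics:
    def make_candidates(self, residues):
        frame = pd.DataFrame(
            [{"residue_index": r, "fold_change": 2.0} for r in residues]
        )
        return enr.CandidateSet(frame, k_requested=len(residues) or 1,
                                threshold=2.0, shortfall=0)

    def test_perfect_recovery(self):
        m = enr.recovery_metrics(self.make_candidates([1, 2, 3]), {1, 2, 3})
        assert m.precision == 1.0 and m.recall == 1.0

    def test_disjoint_sets(self):
        m = enr.recovery_metrics(self.make_candidates([4, 5]), {1, 2})
        assert m.precision == 0.0 and m.recall == 0.0

    def test_empty_candidates_flagged(self):
        m = enr.recovery_metrics(self.make_candidates([]), {1})
        assert not m.precision_defined
        assert m.recall == 0.0

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            enr.recovery_metrics(self.make_candidates([1]), set())
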