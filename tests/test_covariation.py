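import itertools

import numpy as np
import pytest

from cmline.covariation import (
    annotate_alignment,
    category_counts,
    classify_pair,
    covariation_test,
)
from cmline.io_formats import CmlineError
from cmline.simulate import SimulationParams, evolve_alignment, hairpin_structure
from conftest import make_alignment
from oracles import classify_pair_oracle


class TestClassifyPair:
    def test_one_sided_change_is_compatible(self):
        # A-U, A-U, G-U: the G-U wobble keeps pairing with a one-sided change
        c = classify_pair("AAG", "UUU")
        assert c.category == "compatible"
        assert c.canonical_fraction == 1.0

    def test_single_pair_type_is_conserved(self):
        c = classify_pair("G" * 10, "C" * 10)
        assert c.category == "conserved"
        assert c.pairtype_counts == {"GC": 10}

    def test_both_sides_changed_is_covarying(self):
        c = classify_pair("AAGG", "UUCC")
        assert c.category == "covarying"

    def test_non_canonical_majority_is_unsupported(self):
        c = classify_pair("AAAA", "CCCC")  # AC never pairs
        assert c.category == "unsupported"
        assert c.canonical_fraction == 0.0

    def test_exactly_90_percent_canonical_is_unsupported(self):
        # rule is strictly "more than 90%"
        c = classify_pair("A" * 10, "U" * 9 + "C")
        assert c.canonical_fraction == pytest.approx(0.9)
        assert c.category == "unsupported"

    def test_gap_rows_excluded_and_gap_heavy_insufficient(self):
        c = classify_pair("AU-A", "UU-U")
        assert c.n_excluded == 1 and c.n_included == 3
        heavy = classify_pair("A---", "U---")
        assert heavy.category == "insufficient"

    def test_fewer_than_two_rows_insufficient(self):
        assert classify_pair("A", "U").category == "insufficient"

    def test_row_order_invariance(self):
        rng = np.random.default_rng(6)
        alphabet = "ACGU-"
        for _ in range(200):
            n = int(rng.integers(2, 10))
            ci = "".join(alphabet[k] for k in rng.integers(0, 5, n))
            cj = "".join(alphabet[k] for k in rng.integers(0, 5, n))
            perm = rng.permutation(n)
            shuffled_i = "".join(ci[k] for k in perm)
            shuffled_j = "".join(cj[k] for k in perm)
            assert (classify_pair(ci, cj).category
                    == classify_pair(shuffled_i, shuffled_j).category)

    def test_swap_invariance(self):
        rng = np.random.default_rng(16)
        alphabet = "ACGU-"
        for _ in range(200):
            n = int(rng.integers(2, 10))
            ci = "".join(alphabet[k] for k in rng.integers(0, 5, n))
            cj = "".join(alphabet[k] for k in rng.integers(0, 5, n))
            assert classify_pair(ci, cj).category == classify_pair(cj, ci).category

    def test_two_row_sample_against_oracle(self):
        # small spot-check; the exhaustive 3-row sweep runs in the acceptance suite
        alphabet = "ACGU-"
        for r1 in itertools.product(alphabet, repeat=2):
            for r2 in itertools.product(alphabet, repeat=2):
                ci, cj = r1[0] + r2[0], r1[1] + r2[1]
                assert classify_pair(ci, cj).category == classify_pair_oracle(ci, cj)

    def test_repeating_covarying_rows_never_demotes(self):
        ci, cj = "AAGG", "UUCC"
        assert classify_pair(ci, cj).category == "covarying"
        assert classify_pair(ci + "AG", cj + "UC").category == "covarying"


class TestAnnotateAlignment:
    def test_identical_rows_all_conserved(self):
        aln = make_alignment(["GGGAACCC"] * 5, "<<<..>>>")
        cats = category_counts(annotate_alignment(aln))
        assert cats["conserved"] == 3 and cats["covarying"] == 0

    def test_empty_structure_yields_empty(self):
        aln = make_alignment(["ACGU"] * 3, "....")
        assert annotate_alignment(aln) == []

    def test_full_compensation_produces_covariation(self):
        aln, _ = evolve_alignment(SimulationParams(
            n_seqs=30, structure=hairpin_structure(2), subst_rate=0.4,
            compensation_prob=1.0, seed=42))
        cats = category_counts(annotate_alignment(aln))
        assert cats["covarying"] > 0
        assert cats["unsupported"] == 0  # compensation preserves canonicity

    def test_categories_partition_pairs(self):
        aln, _ = evolve_alignment(SimulationParams(
            n_seqs=20, subst_rate=0.3, compensation_prob=0.5, seed=9))
        classifications = annotate_alignment(aln)
        assert sum(category_counts(classifications).values()) == len(classifications)


class TestCovariationTest:
    def test_constant_alignment_nothing_significant(self):
        aln = make_alignment(["GGGAACCC"] * 10, "<<<..>>>")
        results = covariation_test(aln, n_perm=200, seed=1)
        assert all(r.statistic == 0.0 for r in results)
        assert not any(r.significant for r in results)

    def test_perfect_covariation_is_significant(self):
        # half A-U, half G-C at the single annotated pair: a 15/15 split is
        # essentially unattainable under column permutation
        rows = ["A" + "ACGU" + "U"] * 15 + ["G" + "ACGU" + "C"] * 15
        aln = make_alignment(rows, "<....>")
        (result,) = covariation_test(aln, n_perm=1000, seed=3)
        assert result.significant
        assert result.evalue < 0.05

    def test_evalue_monotone_in_statistic(self):
        aln, _ = evolve_alignment(SimulationParams(
            n_seqs=30, subst_rate=0.3, compensation_prob=0.8, seed=21))
        results = covariation_test(aln, n_perm=400, seed=5)
        by_stat = sorted(results, key=lambda r: r.statistic)
        evalues = [r.evalue for r in by_stat]
        assert all(a >= b for a, b in zip(evalues, evalues[1:]))

    def test_significance_flag_matches_threshold(self):
        aln, _ = evolve_alignment(SimulationParams(
            n_seqs=25, subst_rate=0.3, compensation_prob=0.9, seed=31))
        for r in covariation_test(aln, n_perm=300, seed=7, evalue_threshold=0.05):
            assert r.significant == (r.evalue < 0.05)

    def test_same_seed_reproducible(self):
        aln, _ = evolve_alignment(SimulationParams(seed=2))
        a = covariation_test(aln, n_perm=200, seed=11)
        b = covariation_test(aln, n_perm=200, seed=11)
        assert [(r.statistic, r.evalue) for r in a] == [(r.statistic, r.evalue) for r in b]

    def test_too_few_rows_rejected(self):
        aln = make_alignment(["AU"] * 2, "<>")
        with pytest.raises(CmlineError, match="at least 3 rows"):
            covariation_test(aln, seed=1)

    def test_small_n_perm_warns(self):
        aln = make_alignment(["GAC"] * 5, "<.>")
        with pytest.warns(UserWarning, match="n_perm"):
            covariation_test(aln, n_perm=50, seed=1)
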