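import numpy as np
import pytest

from baculokit import repeats
from baculokit.io import reverse_complement
from baculokit.repeats import (RepeatConfig, classify_region,
                               compare_hr_consensuses, count_copies,
                               find_repeat_regions, find_tandem_arrays,
                               palindrome_core, scan_copies, strict_consensus)

import oracles
from conftest import random_dna


class TestFindTandemArrays:
    def test_exact_planted_copies(self):
        rng = np.random.default_rng(0)
        unit = random_dna(rng, 66)
        seq = random_dna(rng, 500) + unit * 5 + random_dna(rng, 500)
        arrays = find_tandem_arrays(seq)
        match = [a for a in arrays if a.period == 66 and a.n_copies == 5]
        assert len(match) == 1
        assert match[0].mean_divergence == 0.0
        assert match[0].consensus == unit

    def test_mutated_copies_recovered(self):
        rng = np.random.default_rng(1)
        unit = random_dna(rng, 66)
        copies = []
        for _ in range(13):
            chars = list(unit)
            for i in rng.choice(66, size=2, replace=False):
                chars[i] = "ACGT"[(("ACGT".index(chars[i]) + 1) % 4)]
            copies.append("".join(chars))
        seq = random_dna(rng, 400) + "".join(copies) + random_dna(rng, 400)
        arrays = find_tandem_arrays(seq)
        assert any(a.period == 66 and a.n_copies == 13 for a in arrays)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_naive_oracle_on_random_sequence(self, seed):
        rng = np.random.default_rng(seed + 100)
        seq = random_dna(rng, 10_000)
        mine = find_tandem_arrays(seq, 20, 80, min_copies=3,
                                  max_divergence=0.1)
        naive = oracles.tandem_arrays_naive(seq, 20, 80, 3, 0.1)
        got = sorted(((a.span[0] - 1, a.span[1] - 1), a.period, a.n_copies)
                     for a in mine)
        assert got == naive

    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError):
            find_tandem_arrays("ACGT" * 100, 50, 20)
        with pytest.raises(ValueError):
            find_tandem_arrays("ACGT" * 100, 10, 20, min_copies=1)


class TestStrictConsensus:
    @pytest.mark.parametrize("copies,threshold,expected", [
        (["ACGT", "ACGT"], 0.25, "ACGT"),
        (["AA", "AG"], 0.25, "AR"),
        (["CT", "CA", "CG"], 0.25, "CD"),
        (["AC", "A-"], 0.25, "AC"),      # gaps are uninformative
    ])
    def test_examples(self, copies, threshold, expected):
        assert strict_consensus(copies, threshold) == expected

    def test_threshold_drops_rare_bases(self):
        copies = ["A"] * 9 + ["G"]
        assert strict_consensus(copies, 0.25) == "A"
        assert strict_consensus(copies, 0.05) == "R"

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        copies = [random_dna(rng, 30) for _ in range(5)]
        cons = strict_consensus(copies)
        assert strict_consensus([cons, cons]) == cons

    def test_zero_columns_errors(self):
        with pytest.raises(ValueError):
            strict_consensus(["", ""])


class TestPalindromeCore:
    def test_perfect_palindrome_scores_zero(self):
        rng = np.random.default_rng(3)
        half = random_dna(rng, 15)
        core = half + reverse_complement(half)
        cons = random_dna(rng, 18) + core + random_dna(rng, 18)
        result = palindrome_core(cons, 30, 4)
        assert result == (18, 0)

    def test_poly_a_has_no_core(self):
        assert palindrome_core("A" * 30, 30, 6) is None
        # every one of the 15 mirror pairs is A vs complement(A)=T
        assert oracles.palindrome_scan("A" * 30, 30) == [(0, 15)]

    def test_odd_core_length_rejected(self):
        with pytest.raises(ValueError):
            palindrome_core("ACGTACGTACGT", 7, 2)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed + 50)
        cons = random_dna(rng, 40)
        per_window = oracles.palindrome_scan(cons, 10)
        best_mm = min(mm for _, mm in per_window)
        expected = next((off, mm) for off, mm in per_window if mm == best_mm)
        assert palindrome_core(cons, 10, max_mismatch=5) == \
            (expected if best_mm <= 5 else None)

    def test_invariant_under_reverse_complement(self):
        rng = np.random.default_rng(4)
        half = random_dna(rng, 15)
        cons = random_dna(rng, 10) + half + reverse_complement(half) \
            + random_dna(rng, 20)
        fwd = palindrome_core(cons, 30, 4)
        rev = palindrome_core(reverse_complement(cons), 30, 4)
        assert fwd is not None and rev is not None
        assert fwd[1] == rev[1]
        assert rev[0] == len(cons) - 30 - fwd[0]


class TestClassifyRegion:
    def _element(self, seq_copies, period):
        cons = strict_consensus(seq_copies)
        spans = [(1 + i * period, (i + 1) * period, False)
                 for i in range(len(seq_copies))]
        return repeats.RepeatElement(spans, period, cons, 0.0)

    def test_ac_rich_alphabet(self):
        el = self._element(["AMACAMACAMAC".replace("M", "A"),
                            "AMACAMACAMAC".replace("M", "C")], 12)
        assert el.consensus == "AMACAMACAMAC"
        assert classify_region(el).klass == "ac_rich"

    def test_palindromic_element_is_hr(self):
        rng = np.random.default_rng(5)
        half = random_dna(rng, 15)
        unit = random_dna(rng, 18) + half + reverse_complement(half) \
            + random_dna(rng, 18)
        el = self._element([unit, unit], 66)
        region = classify_region(el)
        assert region.klass == "hr"
        assert region.palindrome == (18, 0)

    def test_short_nonpalindromic_element_is_non_hr(self):
        unit = "AAAGTGATGATTCATGGTAGAGCAAGGTG"  # 29 bp, no 30 bp core fits
        el = self._element([unit, unit], 29)
        assert classify_region(el).klass == "non_hr"


class TestCountCopies:
    def test_exact_concatenated_copies(self):
        rng = np.random.default_rng(6)
        unit = random_dna(rng, 20)
        assert count_copies(unit * 3, unit) == 3

    def test_truncated_terminal_counts_as_one(self):
        rng = np.random.default_rng(7)
        unit = random_dna(rng, 20)
        seq = unit * 3 + unit[:10]
        assert count_copies(seq, unit, trunc_min_fraction=0.5) == 4
        spans = scan_copies(seq, unit, trunc_min_fraction=0.5)
        assert spans[-1] == (61, 70, True)

    def test_incompatible_sequence_counts_zero(self):
        assert count_copies("G" * 50, "A" * 10, max_mismatches=1) == 0

    def test_iupac_consensus_matches_either_base(self):
        assert count_copies("AAAC" + "AAAT", "AAAY", max_mismatches=0) == 2


class TestCompareHrConsensuses:
    def test_identical_consensuses(self):
        rng = np.random.default_rng(8)
        unit = random_dna(rng, 66)
        el = repeats.RepeatElement([(1, 66, False)], 66, unit, 0.0)
        regions = [repeats.RepeatRegion("hr1", "hr", (1, 66), el),
                   repeats.RepeatRegion("hr2", "hr", (100, 165), el)]
        mat, merged = compare_hr_consensuses(regions)
        assert mat[0, 1] == 1.0 and merged == unit

    def test_single_difference(self):
        rng = np.random.default_rng(9)
        unit = random_dna(rng, 66)
        other = ("A" if unit[0] != "A" else "C") + unit[1:]
        e1 = repeats.RepeatElement([(1, 66, False)], 66, unit, 0.0)
        e2 = repeats.RepeatElement([(1, 66, False)], 66, other, 0.0)
        mat, _ = compare_hr_consensuses([
            repeats.RepeatRegion("hr1", "hr", (1, 66), e1),
            repeats.RepeatRegion("hr2", "hr", (1, 66), e2)])
        assert mat[0, 1] == pytest.approx(65 / 66)

    def test_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(10)
        els = [repeats.RepeatElement([(1, 66, False)], 66,
                                     random_dna(rng, 66), 0.0)
               for _ in range(4)]
        regions = [repeats.RepeatRegion(f"hr{i}", "hr", (1, 66), e)
                   for i, e in enumerate(els)]
        mat, _ = compare_hr_consensuses(regions)
        assert np.allclose(mat, mat.T) and np.allclose(np.diag(mat), 1.0)

    def test_length_mismatch_errors(self):
        e1 = repeats.RepeatElement([(1, 10, False)], 10, "ACGTACGTAC", 0.0)
        e2 = repeats.RepeatElement([(1, 12, False)], 12, "ACGTACGTACGT", 0.0)
        with pytest.raises(ValueError):
            compare_hr_consensuses([
                repeats.RepeatRegion("a", "hr", (1, 10), e1),
                repeats.RepeatRegion("b", "hr", (1, 12), e2)])


class TestRegionRecovery:
    def test_planted_regions_recovered(self, small_genome):
        record, manifest = small_genome
        regions = find_repeat_regions(record.sequence)
        planted = sorted(manifest.repeats, key=lambda r: r.span)
        assert len(regions) == len(planted)
        for found, truth in zip(regions, planted):
            assert found.klass == truth.klass
            assert found.element.period == truth.period
            assert found.element.n_copies == truth.n_copies
            assert sum(c[2] for c in found.element.copies) == 1
            assert not (found.span[1] < truth.span[0]
                        or found.span[0] > truth.span[1])

    @pytest.mark.parametrize("seed", range(10))
    def test_no_false_hr_on_random_sequence(self, seed):
        rng = np.random.default_rng(seed + 300)
        seq = random_dna(rng, 10_000)
        regions = find_repeat_regions(seq)
        assert [r for r in regions if r.klass == "hr"] == []
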