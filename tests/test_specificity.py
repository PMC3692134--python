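"""Mutant enumeration, flexibility filtering, PFMs and the pipeline."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import structmotif as sm
from structmotif.specificity import (SpecificityError, mutant_count,
                                     records_to_tsv)

from conftest import brute_force_dg


class TestEnumerateMutants:
    @pytest.mark.parametrize("w,k,include,expected", [
        (6, 2, False, 153),
        (10, 2, False, 435),
        (6, 4, True, 1909),
        (10, 4, True, 20686),
        (1, 1, False, 3),
        (4, 1, True, 13),
    ])
    def test_counts(self, w, k, include, expected):
        native = ("ACGT" * 3)[:w]
        seqs = sm.enumerate_mutants(native, None, k, include_native=include)
        assert len(seqs) == expected
        assert len(set(seqs)) == expected

    def test_lexicographic_and_hamming(self):
        native = "ACG"
        seqs = sm.enumerate_mutants(native, None, 2)
        assert seqs == sorted(seqs)
        for s in seqs:
            ham = sum(a != b for a, b in zip(s, native))
            assert 1 <= ham <= 2

    def test_positions_restrict_mutations(self):
        seqs = sm.enumerate_mutants("AAAA", (2, 3), 1)
        assert all(s[0] == "A" and s[3] == "A" for s in seqs)
        assert len(seqs) == 6

    def test_range_outside_sequence_rejected(self):
        with pytest.raises(SpecificityError):
            sm.enumerate_mutants("ACGT", (2, 9), 1)

    @given(w=st.integers(1, 8), k=st.integers(1, 3),
           include=st.booleans())
    def test_closed_form_count(self, w, k, include):
        native = ("GATC" * 2)[:w]
        k = min(k, w)
        seqs = sm.enumerate_mutants(native, None, k, include_native=include)
        assert len(seqs) == mutant_count(w, k, include)


def make_records(native_dg, mutant_dgs):
    records = [sm.MutantRecord("N" * 4, 0, native_dg, 0.0, 0.0)]
    for i, dg in enumerate(mutant_dgs):
        records.append(sm.MutantRecord(f"M{i}xx", 1, dg, dg - native_dg, 0.1))
    return records


class TestFlexibilityFilter:
    def test_worked_example_negative_minimum(self):
        # native -10, mutants {-12, -9, -7}: T = 2, so -7 (ddg = 3) rejected
        records = sm.flexibility_filter(make_records(-10, [-12, -9, -7]), -10)
        assert [r.selected for r in records] == [True, True, True, False]

    def test_worked_example_all_mutants_worse(self):
        # native -10, mutants {-8, -5}: T = 2, only -8 and the native pass
        records = sm.flexibility_filter(make_records(-10, [-8, -5]), -10)
        assert [r.selected for r in records] == [True, True, False]

    def test_single_mutant_always_selected(self):
        records = sm.flexibility_filter(make_records(-10, [-3]), -10)
        assert all(r.selected for r in records)

    def test_empty_mutant_list_warns_and_keeps_native(self):
        records = [sm.MutantRecord("ACGT", 0, -5.0, 0.0, 0.0)]
        with pytest.warns(UserWarning):
            out = sm.flexibility_filter(records, -5.0)
        assert out[0].selected

    @given(shift=st.floats(-50, 50, allow_nan=False))
    def test_shift_invariance(self, shift):
        base = sm.flexibility_filter(make_records(-10, [-12, -9, -7]), -10)
        shifted = sm.flexibility_filter(
            make_records(-10 + shift, [-12 + shift, -9 + shift, -7 + shift]),
            -10 + shift)
        assert [r.selected for r in base] == [r.selected for r in shifted]


class TestBuildPfm:
    def test_one_hot_single_sequence(self):
        pfm = sm.build_pfm(["ACGT"])
        assert np.array_equal(pfm.frequencies, np.eye(4))

    def test_two_sequences(self):
        pfm = sm.build_pfm(["AA", "AC"])
        assert np.allclose(pfm.frequencies[0], [1, 0, 0, 0])
        assert np.allclose(pfm.frequencies[1], [0.5, 0.5, 0, 0])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(SpecificityError):
            sm.build_pfm(["ACGT", "ACG"])

    def test_all_sequences_give_uniform_pfm(self):
        w = 3
        seqs = ["".join(p) for p in itertools.product("ACGT", repeat=w)]
        pfm = sm.build_pfm(seqs)
        assert np.allclose(pfm.frequencies, 0.25, atol=1e-12)


class TestScorePfm:
    def test_uniform_pfm_constant_score(self):
        w = 5
        pfm = sm.Pfm(np.full((w, 5 - 1), 0.25))
        expected = w * math.log2((0.25 + 0.01) / 0.25)
        for seq in ("AAAAA", "CGTAC", "TTTTT"):
            assert sm.score_pfm(pfm, seq) == pytest.approx(expected)

    def test_one_hot_pfm_maximal_on_its_sequence(self):
        target = "GATA"
        pfm = sm.build_pfm([target])
        best = sm.score_pfm(pfm, target)
        for other in itertools.product("ACGT", repeat=4):
            s = "".join(other)
            if s != target:
                assert sm.score_pfm(pfm, s) < best

    def test_hand_value_single_column(self):
        pfm = sm.Pfm(np.array([[0.5, 0.5, 0.0, 0.0]]))
        assert sm.score_pfm(pfm, "A") == pytest.approx(math.log2(0.51 / 0.25))

    def test_short_tail_shrinks_effective_width(self):
        pfm = sm.build_pfm(["ACGT"])
        # aligning position 3 leaves only 2 positions of overlap: PFM
        # columns 1-2 (one-hot A, C) meet "G", "T" -> two mismatches
        two = sm.score_pfm(pfm, "ACGT", k=3)
        assert two == pytest.approx(2 * math.log2(0.01 / 0.25))

    def test_reverse_complement_mode(self):
        pfm = sm.build_pfm(["AAAA"])
        fwd = sm.score_pfm(pfm, "TTTT")
        both = sm.score_pfm(pfm, "TTTT", consider_rc=True)
        assert both > fwd
        assert both == pytest.approx(sm.score_pfm(pfm, "AAAA"))

    def test_scan_mode_finds_embedded_site(self):
        pfm = sm.build_pfm(["GATA"])
        assert sm.score_pfm(pfm, "CCGATACC", scan=True) == pytest.approx(
            sm.score_pfm(pfm, "GATA"))

    def test_offset_out_of_range(self):
        pfm = sm.build_pfm(["ACGT"])
        with pytest.raises(SpecificityError):
            sm.score_pfm(pfm, "ACGT", k=9)

    @given(j=st.integers(0, 3), boost=st.floats(0.05, 0.4))
    def test_monotone_in_matching_frequency(self, j, boost):
        seq = "ACGT"
        freq = np.full((4, 4), 0.25)
        base_idx = "ACGT".index(seq[j])
        lo = sm.score_pfm(sm.Pfm(freq), seq)
        freq2 = freq.copy()
        freq2[j] -= boost / 3.0
        freq2[j, base_idx] = 0.25 + boost
        hi = sm.score_pfm(sm.Pfm(freq2), seq)
        assert hi >= lo


class TestRandomSites:
    def test_reproducible_under_seed(self):
        assert sm.random_sites(50, 9, seed=1) == sm.random_sites(50, 9, seed=1)
        assert sm.random_sites(50, 9, seed=1) != sm.random_sites(50, 9, seed=2)

    def test_shape(self):
        sites = sm.random_sites(10000, 9, seed=1)
        assert len(sites) == 10000
        assert all(len(s) == 9 for s in sites)

    def test_base_frequencies_uniform(self):
        sites = sm.random_sites(100000, 1, seed=3)
        counts = {b: 0 for b in "ACGT"}
        for s in sites:
            counts[s] += 1
        for b in "ACGT":
            assert abs(counts[b] / 100000 - 0.25) < 0.005


@pytest.fixture(scope="module")
def result(duplex_complex, potential, templates):
    dup = sm.detect_dsdna(duplex_complex)[0]
    return sm.run_pipeline(duplex_complex, dup, potential, templates,
                           positions=(2, 5), max_mutations=1)


class TestPipeline:
    def test_record_count_four_bp_site(self, result):
        assert len(result.records) == 13  # 4 positions x 3 + native

    def test_native_record_invariants(self, result):
        native = next(r for r in result.records if r.n_mutations == 0)
        assert native.ddg == 0.0
        assert native.rmsd == 0.0
        assert native.selected

    def test_ddg_matches_independent_recomputation(
            self, result, duplex_complex, potential, templates):
        dup = sm.detect_dsdna(duplex_complex)[0]
        native_site = result.native_sequence
        for r in result.records[:6]:
            if r.n_mutations == 0:
                continue
            mutated = duplex_complex
            for i, (a, b) in enumerate(zip(native_site, r.sequence)):
                if a != b:
                    mutated = sm.mutate_pair(
                        mutated, dup, result.positions[0] - 1 + i,
                        b + "<->" + {"A": "T", "T": "A", "C": "G",
                                     "G": "C"}[b], templates)
            oracle = brute_force_dg(mutated, potential)
            assert r.dg == pytest.approx(oracle, abs=1e-9)
            assert r.ddg == pytest.approx(oracle - result.native_dg, abs=1e-9)

    def test_sorted_by_ddg_with_native_at_zero(self, result):
        ddgs = [r.ddg for r in result.records]
        assert ddgs == sorted(ddgs)
        native_pos = next(i for i, r in enumerate(result.records)
                          if r.n_mutations == 0)
        assert all(d < 0 for d in ddgs[:native_pos])

    def test_selection_threshold_consistency(self, result):
        mutants = [r for r in result.records if r.n_mutations > 0]
        threshold = abs(min(r.ddg for r in mutants))
        for r in result.records:
            assert r.selected == (r.ddg <= threshold)

    def test_pfm_columns_stochastic(self, result):
        assert np.allclose(result.pfm.frequencies.sum(axis=1), 1.0,
                           atol=1e-12)

    def test_every_record_has_pfm_score(self, result):
        assert all(math.isfinite(r.pfm_score) for r in result.records)

    def test_tsv_export_round_numbers(self, result):
        tsv = records_to_tsv(result.records)
        lines = tsv.strip().splitlines()
        assert lines[0].startswith("sequence\t")
        assert len(lines) == len(result.records) + 1


class TestSortRecords:
    def test_tie_break_by_sequence(self):
        records = [sm.MutantRecord(s, 1, 0.0, 0.0, 0.0)
                   for s in ("TTTT", "AAAA", "CCCC")]
        out = sm.sort_records(records, "ddg")
        assert [r.sequence for r in out] == ["AAAA", "CCCC", "TTTT"]

    def test_unknown_column_rejected(self):
        with pytest.raises(SpecificityError):
            sm.sort_records([], "energy")
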