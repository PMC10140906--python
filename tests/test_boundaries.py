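"""TIR pair discovery vs the exhaustive enumeration oracle; TSD selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_tir_pairs, revcomp
from pbmine.boundaries import find_tir_pairs, select_element

ARM = "CACTATTGACGTGCA"  # 15 bp


def _pairs_as_tuples(pairs):
    return sorted((p.left_start, p.right_end, p.arm_length, p.mismatches)
                  for p in pairs)


class TestFindTirPairs:
    def test_planted_perfect_pair(self, rng):
        core = "".join(rng.choice(list("ACGT"), size=120))
        locus = "N" * 20 + ARM + core + revcomp(ARM) + "N" * 20
        pairs = find_tir_pairs(locus, max_mismatch=0, search_window=40)
        best = max(pairs, key=lambda p: p.arm_length)
        assert best.arm_length == 15
        assert best.mismatches == 0
        assert best.left_start == 20
        assert best.right_end == len(locus) - 20

    def test_homopolymer_has_no_pairs(self):
        assert find_tir_pairs("A" * 200) == []

    def test_mismatch_budget_respected(self, rng):
        core = "".join(rng.choice(list("ACGT"), size=100))
        right = list(revcomp(ARM))
        right[7] = {"A": "C", "C": "A", "G": "T", "T": "G"}[right[7]]
        locus = "GGGG" + ARM + core + "".join(right) + "CCCC"
        with_budget = find_tir_pairs(locus, max_mismatch=2, search_window=30)
        l15 = [p for p in with_budget
               if p.left_start == 4 and p.arm_length >= 14]
        assert l15 and l15[0].mismatches >= 1
        none_allowed = find_tir_pairs(locus, max_mismatch=0, search_window=30)
        assert all(
            not (p.left_start == 4 and p.arm_length >= 14) for p in none_allowed
        )

    def test_too_short_locus_raises(self):
        with pytest.raises(ValueError):
            find_tir_pairs("ACGTAGCTA", min_len=10)

    def test_matches_oracle_on_random_loci(self, rng):
        for _ in range(40):
            n = int(rng.integers(60, 500))
            locus = "".join(rng.choice(list("ACGT"), size=n))
            got = _pairs_as_tuples(find_tir_pairs(locus, min_len=6, max_len=50,
                                                  max_mismatch=2))
            want = sorted(brute_tir_pairs(locus, min_len=6, max_len=50,
                                          max_mismatch=2))
            assert got == want

    def test_matches_oracle_with_planted_arms(self, rng):
        for trial in range(20):
            n = int(rng.integers(150, 400))
            locus = list("".join(rng.choice(list("ACGT"), size=n)))
            arm = "".join(rng.choice(list("ACGT"), size=int(rng.integers(8, 20))))
            locus[5 : 5 + len(arm)] = arm
            locus[n - 5 - len(arm) : n - 5] = revcomp(arm)
            locus = "".join(locus)
            got = _pairs_as_tuples(find_tir_pairs(locus, min_len=8, max_len=60,
                                                  max_mismatch=2))
            want = sorted(brute_tir_pairs(locus, min_len=8, max_len=60,
                                          max_mismatch=2))
            assert got == want

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_oracle_equivalence_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(40, 300))
        locus = "".join(rng.choice(list("ACGT"), size=n))
        got = _pairs_as_tuples(find_tir_pairs(locus, min_len=5, max_len=40,
                                              max_mismatch=1))
        want = sorted(brute_tir_pairs(locus, min_len=5, max_len=40,
                                      max_mismatch=1))
        assert got == want

    def test_reverse_complement_symmetry(self, rng):
        locus = "".join(rng.choice(list("ACGT"), size=300))
        fwd = _pairs_as_tuples(find_tir_pairs(locus, min_len=6, max_mismatch=1))
        rev = find_tir_pairs(revcomp(locus), min_len=6, max_mismatch=1)
        n = len(locus)
        mirrored = sorted((n - p.right_end, n - p.left_start, p.arm_length,
                           p.mismatches) for p in rev)
        assert fwd == mirrored

    def test_long_tir_frac_budget(self, rng):
        arm = "".join(rng.choice(list("ACGT"), size=200))
        right = list(revcomp(arm))
        for i in (10, 60, 110, 160, 190):  # 5 mismatches over 200 bp
            right[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[right[i]]
        core = "".join(rng.choice(list("ACGT"), size=400))
        locus = "TTAA" + arm + core + "".join(right) + "TTAA"
        strict = find_tir_pairs(locus, max_mismatch=2, search_window=250)
        assert all(p.arm_length < 150 for p in strict)
        relaxed = find_tir_pairs(locus, max_mismatch=2, mismatch_frac=0.05,
                                 search_window=250)
        assert any(p.arm_length >= 195 for p in relaxed)


class TestSelectElement:
    # "AAA" walls flanking the core stop chance inward arm extension, and
    # "CCC"/"GGG" walls outside stop outward pairs from crossing the TSD.
    def _locus(self, rng, left_flank="TTAA", right_flank="TTAA", arm=ARM):
        core = "AAA" + "".join(rng.choice(list("ACGT"), size=200)) + "AAA"
        pad = "".join(rng.choice(list("ACGT"), size=13)) + "CCC"
        pad2 = "CCC" + "".join(rng.choice(list("ACGT"), size=13))
        return pad + left_flank + arm + core + revcomp(arm) + right_flank + pad2

    def test_canonical_selection(self, rng):
        locus = self._locus(rng)
        pairs = find_tir_pairs(locus, max_mismatch=0, search_window=50)
        b = select_element(pairs, locus)
        assert b is not None
        assert (b.left_tsd, b.right_tsd) == ("TTAA", "TTAA")
        assert b.tsd_canonical
        assert b.tir.arm_length == 15

    def test_canonical_beats_longer_noncanonical(self, rng):
        # two planted pairs: a long one with random flanks, a short TTAA one;
        # AAA/CCC walls prevent the pairs from chaining into one long arm
        long_arm = "".join(rng.choice(list("ACGT"), size=25))
        while "TTAA" in long_arm:  # avoid accidental canonical sub-pairs
            long_arm = "".join(rng.choice(list("ACGT"), size=25))
        short_arm = "CACTAGGCAT"
        sp1 = "CCC" + "".join(rng.choice(list("ACGT"), size=8))
        sp2 = "".join(rng.choice(list("ACGT"), size=8)) + "CCC"
        core = "AAA" + "".join(rng.choice(list("ACGT"), size=150)) + "AAA"
        locus = ("GGCA" + long_arm + sp1 + "TTAA" + short_arm + core
                 + revcomp(short_arm) + "TTAA" + sp2 + revcomp(long_arm)
                 + "GGCA")
        # window must admit both pairs' outer starts
        pairs = find_tir_pairs(locus, min_len=8, max_mismatch=0,
                               search_window=60)
        arms = {p.arm_length for p in pairs}
        assert 25 in arms and 10 in arms
        b = select_element(pairs, locus)
        assert b.tsd_canonical
        assert b.tir.arm_length == 10

    def test_mutated_equal_flanks_selected_as_noncanonical(self, rng):
        locus = self._locus(rng, left_flank="TTGA", right_flank="TTGA")
        pairs = find_tir_pairs(locus, max_mismatch=0, search_window=50)
        b = select_element(pairs, locus)
        assert b is not None
        assert not b.tsd_canonical
        assert b.left_tsd == b.right_tsd == "TTGA"

    def test_unequal_flanks_rejected(self, rng):
        locus = self._locus(rng, left_flank="GGGG", right_flank="CCCC")
        pairs = [p for p in find_tir_pairs(locus, max_mismatch=0,
                                           search_window=50)
                 if p.arm_length == 15]
        assert select_element(pairs, locus) is None

    def test_edge_pairs_skipped(self, rng):
        core = "AAA" + "".join(rng.choice(list("ACGT"), size=160)) + "AAA"
        locus = ARM + core + revcomp(ARM)
        pairs = find_tir_pairs(locus, max_mismatch=0,
                               search_window=len(ARM) + 2)
        assert pairs  # the planted pair is found ...
        # ... but its flanking 4-mers are unreadable at the locus edge
        assert select_element(pairs, locus) is None
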