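"""Identity matrices, NJ correctness on additive inputs, clade assignment,
TIR logos."""

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import global_identity
from pbmine.comparative import (
    IdentityMatrix,
    assign_clades,
    identity_matrix,
    identity_summary,
    nj_tree,
    pairwise_identity,
    tir_logo,
)


class TestPairwiseIdentity:
    def test_identical(self):
        seq = "MKVLATNWQRPDEFGHIKLY" * 5
        assert pairwise_identity(seq, seq) == 100.0

    def test_single_substitution_in_100(self):
        a = "MKVLATNWQRPDEFGHIKLY" * 5
        b = a[:50] + ("W" if a[50] != "W" else "Y") + a[51:]
        assert pairwise_identity(a, b) == pytest.approx(99.0)

    def test_score_matches_dp_oracle(self, rng):
        # optimal alignments may tie, so identity of an arbitrary co-optimal
        # path is not unique -- the optimal *score* is, and must agree
        from oracles import needleman_wunsch
        from pbmine.seeding import make_protein_aligner

        aligner = make_protein_aligner(mode="global")
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(5):
            a = "".join(rng.choice(aas, size=60))
            b = "".join(rng.choice(aas, size=55))
            score, _, _ = needleman_wunsch(a, b)
            assert aligner.score(a, b) == pytest.approx(score)

    def test_identity_matches_dp_oracle_on_relatives(self, rng):
        # substitution-only relatives: the gap-free alignment is optimal and
        # unique, so identity must equal both the oracle's and the direct
        # positional comparison
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        a = "".join(rng.choice(aas, size=100))
        b = list(a)
        for p in rng.choice(100, size=10, replace=False):
            b[p] = "W" if b[p] != "W" else "Y"
        b = "".join(b)
        assert pairwise_identity(a, b) == pytest.approx(90.0)
        assert global_identity(a, b) == pytest.approx(90.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("MKV", "MKV")


class TestIdentitySummary:
    def test_two_tight_clades(self):
        labels = ("a1", "a2", "b1", "b2")
        m = np.array([
            [100.0, 100.0, 30.0, 30.0],
            [100.0, 100.0, 30.0, 30.0],
            [30.0, 30.0, 100.0, 100.0],
            [30.0, 30.0, 100.0, 100.0],
        ])
        s = identity_summary(IdentityMatrix(labels, m, ("A", "A", "B", "B")))
        assert s.within_by_clade == {"A": 100.0, "B": 100.0}
        assert s.between_mean == pytest.approx(30.0)

    def test_singleton_clade_absent(self):
        labels = ("a1", "a2", "b1")
        m = np.array([[100.0, 90.0, 30.0],
                      [90.0, 100.0, 30.0],
                      [30.0, 30.0, 100.0]])
        s = identity_summary(IdentityMatrix(labels, m, ("A", "A", "B")))
        assert s.within_by_clade["B"] is None
        assert s.within_by_clade["A"] == pytest.approx(90.0)

    def test_single_clade_between_absent(self):
        labels = ("a1", "a2")
        m = np.array([[100.0, 95.0], [95.0, 100.0]])
        s = identity_summary(IdentityMatrix(labels, m, ("A", "A")))
        assert s.between_mean is None

    def test_generated_clades_within_above_between(self, search_refs):
        seqs = [r.sequence for r in search_refs]
        labels = [r.id for r in search_refs]
        clades = [r.clade for r in search_refs]
        s = identity_summary(identity_matrix(seqs, labels, clades))
        assert s.within_mean > s.between_mean


def _tree_distances(tree_str, labels):
    t = dendropy.Tree.get(data=tree_str, schema="newick",
                          preserve_underscores=True)
    pdm = t.phylogenetic_distance_matrix()
    tx = {l.label: l for l in t.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                d[i, j] = pdm.distance(tx[labels[i]], tx[labels[j]])
    return d


class TestNJTree:
    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 5.0, 9.0],
                      [5.0, 0.0, 8.0],
                      [9.0, 8.0, 0.0]])
        t = nj_tree(d, ["A", "B", "C"])
        # three-point formulas: la=(5+9-8)/2=3, lb=(5+8-9)/2=2, lc=(9+8-5)/2=6
        got = _tree_distances(t.newick, ["A", "B", "C"])
        assert np.allclose(got, d)

    def test_four_taxon_additive_recovery(self):
        # tree ((A:2,B:3):1,(C:4,D:5)): additive distances
        d = np.array([
            [0.0, 5.0, 7.0, 8.0],
            [5.0, 0.0, 8.0, 9.0],
            [7.0, 8.0, 0.0, 9.0],
            [8.0, 9.0, 0.0, 0.0],
        ])
        d[3, 2] = d[2, 3] = 9.0
        d[2, 3] = 9.0
        t = nj_tree(d, ["A", "B", "C", "D"])
        got = _tree_distances(t.newick, ["A", "B", "C", "D"])
        assert np.allclose(got, d)

    def test_identical_taxa_zero_branches(self):
        d = np.array([[0.0, 0.0, 4.0],
                      [0.0, 0.0, 4.0],
                      [4.0, 4.0, 0.0]])
        t = nj_tree(d, ["X1", "X2", "Y"])
        got = _tree_distances(t.newick, ["X1", "X2", "Y"])
        assert got[0, 1] == pytest.approx(0.0)

    def test_asymmetric_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            nj_tree(d, ["A", "B"])

    @given(st.integers(0, 10 ** 6))
    @settings(max_examples=20, deadline=None)
    def test_additive_matrices_recover_topology(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        labels = [f"t{i}" for i in range(n)]
        # random binary tree with positive branch lengths -> additive matrix
        taxa = dendropy.TaxonNamespace(labels)
        src = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=n, taxon_namespace=taxa,
            rng=__import__("random").Random(seed),
        )
        for e in src.preorder_edge_iter():
            if e.length is not None:
                e.length = float(rng.uniform(0.1, 2.0))
        pdm = src.phylogenetic_distance_matrix()
        tx = list(src.taxon_namespace)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    d[i, j] = pdm.distance(tx[i], tx[j])
        t = nj_tree(d, [x.label for x in tx])
        got = dendropy.Tree.get(data=t.newick, schema="newick",
                                taxon_namespace=src.taxon_namespace,
                                preserve_underscores=True)
        for tr in (src, got):
            tr.is_rooted = False
            tr.encode_bipartitions()
        rf = dendropy.calculate.treecompare.symmetric_difference(src, got)
        assert rf == 0


class TestAssignClades:
    def _tree(self):
        nwk = ("((q1:0.1,(refA1:0.1,refA2:0.1):0.1):0.5,"
               "((refB1:0.1,q2:0.1):0.1,refB2:0.1):0.5,"
               "(out1:1.0,out2:1.0):2.0);")
        from pbmine.comparative import PhyloTree

        return PhyloTree(newick=nwk, labels=(
            "q1", "refA1", "refA2", "refB1", "q2", "refB2", "out1", "out2"))

    def test_queries_inherit_clades(self):
        refs = {"refA1": "A", "refA2": "A", "refB1": "B", "refB2": "B"}
        got = assign_clades(self._tree(), refs, ["out1", "out2"])
        assert got == {"q1": "A", "q2": "B"}

    def test_no_references_rejected(self):
        with pytest.raises(ValueError):
            assign_clades(self._tree(), {}, ["out1"])

    def test_mixed_cluster_unassigned(self):
        from pbmine.comparative import PhyloTree

        nwk = ("((q1:0.1,(refA1:0.1,refB1:0.1):0.1):0.5,"
               "(refA2:0.1,refB2:0.1):0.5,out1:2.0);")
        t = PhyloTree(newick=nwk,
                      labels=("q1", "refA1", "refB1", "refA2", "refB2", "out1"))
        refs = {"refA1": "A", "refA2": "A", "refB1": "B", "refB2": "B"}
        got = assign_clades(t, refs, ["out1"])
        assert got["q1"] == "unassigned"


class TestTirLogo:
    def test_identical_tirs_full_information(self):
        logo = tir_logo(["CACTAGGT"] * 10)
        assert np.allclose(logo.information_content, 2.0)
        assert logo.consensus == "CACTAGGT"

    def test_uniform_column_zero_information(self):
        logo = tir_logo(["A", "C", "G", "T"])
        assert logo.information_content[0] == pytest.approx(0.0)

    def test_columns_sum_to_one(self, rng):
        tirs = ["".join(rng.choice(list("ACGT"), size=12)) for _ in range(20)]
        logo = tir_logo(tirs)
        assert np.allclose(logo.frequencies.sum(axis=1), 1.0)
        assert np.all(logo.information_content >= 0.0)
        assert np.all(logo.information_content <= 2.0)

    def test_noisy_cacta_consensus(self, rng):
        base = "CACTAGTTGGCATG"
        tirs = []
        for _ in range(40):
            t = [c if rng.random() > 0.1
                 else "ACGT"[rng.integers(0, 4)] for c in base]
            tirs.append("".join(t))
        logo = tir_logo(tirs)
        assert logo.consensus[:5] == "CACTA"
        assert logo.n_sequences == 40

    def test_padding_flagged(self):
        logo = tir_logo(["CACTAGG", "CACTA"])
        assert logo.padded

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            tir_logo(["CACTA"])
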