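"""TN93 distances and likelihoods, neighbor joining, progressive alignment,
and bootstrap supports."""

import math

import numpy as np
import pytest

from regprof import phylogeny as T
from regprof.alignment import global_align, simple_dna_scheme

# 120-nt pair with planted purine transitions, pyrimidine transitions and
# transversions.  The expected distance was computed independently with
# R/ape: dist.dna(model = "TN93") -> 0.181763043971.
APE_PAIR_A = (
    "GTTACTATTCCAACGGTTGTAAGAAGCTGGCAAAGACATAATGTGTAGGTCGACCATCTGGGGACACATAG"
    "CTGATTTGAATGATGGCCAATCGCTACAATGCGTCGGCGTTATATTACT"
)
APE_PAIR_B = (
    "ACCGTCGCAGGGGGAAAAATAAGAAGCTGGCAAAGACATAATGTGTAGGTCGACCATCTGGGGACACATAG"
    "CTGATTTGAATGATGGCCAATCGCTACAATGCGTCGGCGTTATATTACT"
)
APE_TN93 = 0.1817630439708364


def quartet_distances():
    """Additive distances from the tree ((A:2,B:3):1,(C:4,D:5))."""
    ids = ["A", "B", "C", "D"]
    D = np.array(
        [
            [0, 5, 7, 8],
            [5, 0, 8, 9],
            [7, 8, 0, 9],
            [8, 9, 9, 0],
        ],
        dtype=float,
    )
    return T.DistanceMatrix(ids, D)


def leaf_branch_lengths(tree):
    out = {}

    def walk(node):
        for child, length in node.children:
            if child.is_leaf():
                out[child.name] = length
            walk(child)

    walk(tree.root)
    return out


class TestTN93Distance:
    def test_identical_sequences_have_zero_distance(self):
        assert T.tn93_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_matches_independent_closed_form(self):
        d = T.tn93_distance(APE_PAIR_A, APE_PAIR_B)
        assert abs(d - APE_TN93) < 1e-9

    def test_symmetry(self):
        assert T.tn93_distance(APE_PAIR_A, APE_PAIR_B) == T.tn93_distance(
            APE_PAIR_B, APE_PAIR_A
        )

    def test_reduces_to_k2p_under_uniform_composition(self):
        # compensating substitutions keep the pooled base composition uniform
        a = "ACGT" * 10
        b = list(a)
        b[0] = "G"   # A->G      (purine transition)
        b[2] = "A"   # G->A      (purine transition)
        b[1] = "T"   # C->T      (pyrimidine transition)
        b[3] = "C"   # T->C      (pyrimidine transition)
        b[4] = "C"   # A->C      (transversion)
        b[5] = "A"   # C->A      (transversion)
        b = "".join(b)
        P, Q = 4 / 40, 2 / 40
        k2p = 0.5 * math.log(1 / (1 - 2 * P - Q)) + 0.25 * math.log(1 / (1 - 2 * Q))
        assert T.tn93_distance(a, b) == pytest.approx(k2p, abs=1e-12)

    def test_monotone_in_added_substitutions(self):
        rng = np.random.default_rng(30)
        a = "".join(rng.choice(list("ACGT"), size=400))
        b = list(a)
        prev = 0.0
        flip = {"A": "G", "G": "A", "C": "T", "T": "C"}
        sites = rng.permutation(400)
        for batch in range(5):
            for i in sites[batch * 20 : (batch + 1) * 20]:
                b[i] = flip[a[i]]
            d = T.tn93_distance(a, "".join(b))
            assert d > prev
            prev = d

    def test_gapped_sites_are_skipped_pairwise(self):
        assert T.tn93_distance("AC-TACGT", "ACNTACGT") == 0.0

    def test_saturation_returns_inf(self):
        a = "ACGT" * 15
        b = "GTAC" * 15  # every site substituted by a transition
        assert math.isinf(T.tn93_distance(a, b))

    def test_no_comparable_sites_is_an_error(self):
        with pytest.raises(ValueError, match="comparable"):
            T.tn93_distance("---", "AAA")


class TestNeighborJoining:
    def test_recovers_additive_quartet_exactly(self):
        tree = T.nj_tree(quartet_distances())
        splits = tree.bipartitions()
        assert frozenset({"C", "D"}) in splits
        assert splits[frozenset({"C", "D"})] == pytest.approx(1.0)
        lengths = leaf_branch_lengths(tree)
        assert lengths == pytest.approx({"A": 2.0, "B": 3.0, "C": 4.0, "D": 5.0})

    def test_three_taxa_closed_form(self):
        D = T.DistanceMatrix(["A", "B", "C"], np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        tree = T.nj_tree(D)
        assert leaf_branch_lengths(tree) == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_topology_stable_under_small_perturbation(self):
        rng = np.random.default_rng(31)
        base = quartet_distances()
        for _ in range(10):
            noise = rng.uniform(-0.01, 0.01, size=(4, 4))
            noise = (noise + noise.T) / 2
            np.fill_diagonal(noise, 0.0)
            D = T.DistanceMatrix(base.ids, base.values + noise)
            tree = T.nj_tree(D)
            assert frozenset({"C", "D"}) in tree.bipartitions(resolved_only=False)

    def test_saturated_entries_are_rejected_by_name(self):
        D = quartet_distances()
        D.values[0, 1] = D.values[1, 0] = np.inf
        with pytest.raises(ValueError, match="A"):
            T.nj_tree(D)

    def test_matches_skbio_topology_on_random_matrix(self):
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(32)
        n = 6
        coords = rng.random((n, 3)) * 5
        D = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        ids = [f"t{i}" for i in range(n)]
        ours = T.nj_tree(T.DistanceMatrix(ids, D))
        theirs = skbio_nj(skbio.DistanceMatrix(D, ids))
        ours_splits = set(ours.bipartitions(resolved_only=False))
        anchor = min(ids)
        theirs_splits = set()
        for node in theirs.non_tips():
            below = {t.name for t in node.tips()}
            if 2 <= len(below) <= n - 2:
                side = below if anchor not in below else set(ids) - below
                theirs_splits.add(frozenset(side))
        assert ours_splits == theirs_splits


class TestTN93Likelihood:
    PARAMS = T.TN93Params((0.3, 0.2, 0.2, 0.3), alpha1=0.8, alpha2=0.5, beta=0.3)

    def test_transition_matrix_rows_sum_to_one(self):
        P = self.PARAMS.transition_matrix(0.7)
        assert np.allclose(P.sum(axis=1), 1.0)
        assert (P >= 0).all()

    def test_detailed_balance(self):
        P = self.PARAMS.transition_matrix(0.4)
        pi = self.PARAMS.pi
        flow = pi[:, None] * P
        assert np.allclose(flow, flow.T)

    def test_two_leaves_match_analytic_pairwise_likelihood(self):
        rng = np.random.default_rng(33)
        a = "".join(rng.choice(list("ACGT"), size=50))
        b = "".join(rng.choice(list("ACGT"), size=50))
        t1, t2 = 0.12, 0.3
        tree = T.PhyloTree(
            T.TreeNode(children=[(T.TreeNode(name="x"), t1), (T.TreeNode(name="y"), t2)])
        )
        aln = T.MultipleAlignment({"x": a, "y": b})
        ll = T.tn93_loglik(tree, aln, self.PARAMS)
        P = self.PARAMS.transition_matrix(t1 + t2)
        pi = self.PARAMS.pi
        idx = {c: i for i, c in enumerate("ACGT")}
        expected = sum(math.log(pi[idx[x]] * P[idx[x], idx[y]]) for x, y in zip(a, b))
        assert abs(ll - expected) < 1e-9

    def test_zero_branch_identical_state_gives_log_pi(self):
        tree = T.PhyloTree(
            T.TreeNode(children=[(T.TreeNode(name="x"), 0.0), (T.TreeNode(name="y"), 0.0)])
        )
        aln = T.MultipleAlignment({"x": "A", "y": "A"})
        ll = T.tn93_loglik(tree, aln, self.PARAMS)
        assert ll == pytest.approx(math.log(0.3), abs=1e-12)

    def test_invariant_under_rerooting(self):
        rng = np.random.default_rng(34)
        seqs = {
            name: "".join(rng.choice(list("ACGT"), size=60)) for name in "ABCD"
        }
        aln = T.MultipleAlignment(seqs)

        def make(root_at_u):
            A, B = T.TreeNode(name="A"), T.TreeNode(name="B")
            C, D = T.TreeNode(name="C"), T.TreeNode(name="D")
            if root_at_u:
                V = T.TreeNode(children=[(C, 0.4), (D, 0.5)])
                U = T.TreeNode(children=[(A, 0.2), (B, 0.3), (V, 0.1)])
                return T.PhyloTree(U)
            U = T.TreeNode(children=[(A, 0.2), (B, 0.3)])
            V = T.TreeNode(children=[(C, 0.4), (D, 0.5), (U, 0.1)])
            return T.PhyloTree(V)

        ll_u = T.tn93_loglik(make(True), aln, self.PARAMS)
        ll_v = T.tn93_loglik(make(False), aln, self.PARAMS)
        assert abs(ll_u - ll_v) < 1e-9

    def test_leaf_mismatch_is_an_error(self):
        tree = T.PhyloTree(
            T.TreeNode(children=[(T.TreeNode(name="x"), 0.1), (T.TreeNode(name="z"), 0.1)])
        )
        aln = T.MultipleAlignment({"x": "A", "y": "A"})
        with pytest.raises(ValueError, match="leaves"):
            T.tn93_loglik(tree, aln, self.PARAMS)


class TestProgressiveAlign:
    def test_identical_sequences_align_gap_free(self):
        aln = T.progressive_align({"a": "ACGTACGT", "b": "ACGTACGT", "c": "ACGTACGT"})
        assert aln.length == 8
        assert all("-" not in row for row in aln.rows.values())

    def test_two_sequences_reduce_to_pairwise_global(self, dna_scheme):
        a, b = "ACGTACGTAA", "ACGTCGTAA"
        aln = T.progressive_align({"a": a, "b": b}, dna_scheme)
        pairwise = global_align(a, b, dna_scheme)
        assert aln.rows["a"] == pairwise.aligned_query
        assert aln.rows["b"] == pairwise.aligned_subject

    def test_degapping_recovers_inputs(self):
        rng = np.random.default_rng(35)
        seqs = {}
        base = "".join(rng.choice(list("ACGT"), size=50))
        for i in range(4):
            s = list(base)
            for j in rng.choice(50, size=5, replace=False):
                s[j] = rng.choice(list("ACGT"))
            # an indel-ish variant: drop a few characters
            drop = set(rng.choice(50, size=rng.integers(0, 4), replace=False))
            seqs[f"s{i}"] = "".join(c for k, c in enumerate(s) if k not in drop)
        aln = T.progressive_align(seqs)
        for name, seq in seqs.items():
            assert aln.degapped(name) == seq

    def test_empty_sequence_is_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            T.progressive_align({"a": "ACGT", "b": ""})


class TestBootstrap:
    def make_two_clade_alignment(self, n_per_clade=3, length=200, seed=36):
        rng = np.random.default_rng(seed)
        cladeA = "".join(rng.choice(list("ACGT"), size=length))
        cladeB = list(cladeA)
        for i in rng.choice(length, size=60, replace=False):
            cladeB[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[cladeB[i]]
        cladeB = "".join(cladeB)
        flip = {"A": "G", "G": "A", "C": "T", "T": "C"}
        rows = {}
        for tag, template in (("a", cladeA), ("b", cladeB)):
            for i in range(n_per_clade):
                s = list(template)
                for j in rng.choice(length, size=5, replace=False):
                    s[j] = flip[s[j]]
                rows[f"{tag}{i}"] = "".join(s)
        return T.MultipleAlignment(rows)

    def test_identical_sequences_have_no_resolved_splits(self):
        aln = T.MultipleAlignment({f"s{i}": "ACGTACGTACGT" for i in range(4)})
        tree = T.bootstrap_support(aln, B=5, seed=1)
        assert tree.bootstrap_supports == {}

    def test_single_replicate_gives_all_or_nothing(self):
        aln = self.make_two_clade_alignment()
        tree = T.bootstrap_support(aln, B=1, seed=2)
        assert set(tree.bootstrap_supports.values()) <= {0.0, 100.0}

    def test_two_clades_strongly_supported(self):
        aln = self.make_two_clade_alignment()
        tree = T.bootstrap_support(aln, B=100, seed=3)
        clade_b = frozenset({"b0", "b1", "b2"})
        assert tree.bootstrap_supports[clade_b] >= 95.0

    def test_display_threshold_masks_weak_nodes_only_in_rendering(self):
        aln = self.make_two_clade_alignment()
        tree = T.bootstrap_support(aln, B=50, seed=4, display_threshold=60.0)
        rendered = tree.newick(60.0)
        full = tree.newick(None)
        weak = [v for v in tree.bootstrap_supports.values() if v < 60.0]
        assert rendered.endswith(";")
        if weak:  # masked values still retained on the tree object
            assert len(full) >= len(rendered)
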