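import numpy as np
import pytest

from numtclock import phylo_engine
from numtclock.alignment import Alignment
from numtclock.gtr import GTRModel
from numtclock.tree import Tree, TreeError

from conftest import brute_force_loglik, random_alignment, random_model, random_tree


class TestLogLikelihood:
    def test_single_column_zero_lengths_gives_log_pi(self, gtr_model):
        tree = Tree.from_newick("((A:0,B:0):0,(C:0,D:0):0);")
        aln = Alignment.from_sequences({k: "A" for k in "ABCD"})
        ll = phylo_engine.log_likelihood(tree, aln, gtr_model)
        assert np.isclose(ll, np.log(gtr_model.base_freqs[0]))

    def test_duplicated_column_doubles_contribution(self, four_taxon_tree, gtr_model):
        one = Alignment.from_sequences({"A": "A", "B": "C", "C": "G", "D": "T"})
        two = Alignment.from_sequences({"A": "AA", "B": "CC", "C": "GG", "D": "TT"})
        ll1 = phylo_engine.log_likelihood(four_taxon_tree, one, gtr_model)
        ll2 = phylo_engine.log_likelihood(four_taxon_tree, two, gtr_model)
        assert np.isclose(ll2, 2 * ll1)

    @pytest.mark.parametrize("n_leaves", [3, 4, 5])
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_enumeration(self, n_leaves, seed):
        """Pruning equals the brute-force sum over ancestral assignments."""
        rng = np.random.default_rng(1000 * n_leaves + seed)
        tree = random_tree(rng, n_leaves)
        model = random_model(rng)
        aln = random_alignment(rng, tree.leaf_names(), n_columns=6)
        ll = phylo_engine.log_likelihood(tree, aln, model)
        assert np.isclose(ll, brute_force_loglik(tree, aln, model), rtol=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_invariant_under_rerooting(self, seed):
        """Reversible models give the same likelihood from any rooting."""
        rng = np.random.default_rng(seed)
        tree = random_tree(rng, 5)
        model = random_model(rng)
        aln = random_alignment(rng, tree.leaf_names(), n_columns=40)
        ll = phylo_engine.log_likelihood(tree, aln, model)
        for leaf in tree.leaf_names()[:3]:
            rerooted = tree.root_with_outgroup(leaf)
            assert np.isclose(phylo_engine.log_likelihood(rerooted, aln, model), ll)

    def test_gamma_mixture_changes_likelihood(self, four_taxon_tree, small_alignment):
        plain = phylo_engine.log_likelihood(four_taxon_tree, small_alignment, GTRModel())
        gamma = phylo_engine.log_likelihood(
            four_taxon_tree, small_alignment, GTRModel(gamma_shape=0.4)
        )
        assert gamma != plain

    def test_label_mismatch_raises(self, four_taxon_tree, gtr_model):
        aln = Alignment.from_sequences({"A": "AC", "B": "AC", "C": "AC", "X": "AC"})
        with pytest.raises(TreeError):
            phylo_engine.log_likelihood(four_taxon_tree, aln, gtr_model)


class TestOptimizeBranchLengths:
    def test_improves_or_matches_likelihood(self, four_taxon_tree, small_alignment, gtr_model):
        before = phylo_engine.log_likelihood(four_taxon_tree, small_alignment, gtr_model)
        fitted, after = phylo_engine.optimize_branch_lengths(
            four_taxon_tree, small_alignment, gtr_model
        )
        assert after >= before - 1e-9

    def test_recovers_lengths_on_simulated_data(self):
        """1000-column data on a known 4-taxon tree: each length within 3 SE."""
        rng = np.random.default_rng(7)
        truth = Tree.from_newick("((A:0.08,B:0.15):0.06,(C:0.12,D:0.04):0.09);")
        model = GTRModel()
        L = 1000
        seqs = _simulate_on_tree(truth, model, L, rng)
        aln = Alignment.from_sequences(seqs)
        fitted, _ = phylo_engine.optimize_branch_lengths(truth, aln, model)
        for name in "ABCD":
            est = fitted.find(name).length
            true = truth.find(name).length
            se = 3 * np.sqrt(true / L)
            assert abs(est - true) < se + 0.01

    def test_zero_length_branch_recovered_at_boundary(self):
        rng = np.random.default_rng(0)
        truth = Tree.from_newick("((A:0.0,B:0.05):0.05,(C:0.05,D:0.05):0.05);")
        aln = Alignment.from_sequences(_simulate_on_tree(truth, GTRModel(), 2000, rng))
        fitted, _ = phylo_engine.optimize_branch_lengths(truth, aln, GTRModel())
        assert fitted.find("A").length <= 1e-4

    def test_leaf_order_invariance(self, gtr_model):
        rng = np.random.default_rng(5)
        t1 = Tree.from_newick("((A:0.1,B:0.15):0.05,(C:0.1,D:0.2):0.05);")
        aln = Alignment.from_sequences(_simulate_on_tree(t1, gtr_model, 600, rng))
        t2 = Tree.from_newick("((D:0.1,C:0.1):0.05,(B:0.1,A:0.1):0.05);")
        f1, ll1 = phylo_engine.optimize_branch_lengths(t1, aln, gtr_model)
        f2, ll2 = phylo_engine.optimize_branch_lengths(t2, aln, gtr_model)
        assert np.isclose(ll1, ll2, atol=1e-5)
        for name in "ABCD":
            assert np.isclose(f1.find(name).length, f2.find(name).length, atol=1e-4)


class TestNeighborJoining:
    def test_additive_four_taxon_distances_recover_topology(self):
        """Distances from ((A,B),(C,D)) satisfy the four-point condition."""
        labels = ["A", "B", "C", "D"]
        D = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = phylo_engine.neighbor_joining(D, labels)
        assert tree.has_clade({"A", "B"}) or tree.has_clade({"C", "D"})

    def test_three_taxon_star(self):
        D = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = phylo_engine.neighbor_joining(D, ["A", "B", "C"])
        assert sorted(tree.leaf_names()) == ["A", "B", "C"]
        assert np.isclose(tree.distance("A", "B"), 2.0)

    def test_row_permutation_gives_identical_topology(self):
        rng = np.random.default_rng(11)
        n = 7
        pts = rng.uniform(size=(n, 4))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        labels = [f"L{i}" for i in range(n)]
        base = phylo_engine.neighbor_joining(D, labels)
        perm = rng.permutation(n)
        permuted = phylo_engine.neighbor_joining(D[np.ix_(perm, perm)], [labels[i] for i in perm])
        assert set(base.bipartitions()) == set(permuted.bipartitions())

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            phylo_engine.neighbor_joining(np.array([[0, 1], [2, 0.0]]), ["A", "B"])


class TestAncestralStates:
    def test_all_identical_leaves_zero_lengths(self, gtr_model):
        tree = Tree.from_newick("((A:0,B:0):0,(C:0,D:0):0);")
        aln = Alignment.from_sequences({k: "C" for k in "ABCD"})
        anc = phylo_engine.marginal_ancestral_states(tree, aln, gtr_model)
        for node in tree.postorder():
            if not node.is_leaf:
                assert anc.states[node.index][0] == 1  # C
                assert np.isclose(anc.posteriors[node.index][0, 1], 1.0)

    def test_three_leaf_star_matches_hand_computation(self, gtr_model):
        """Root posterior = normalised pi_s * prod_tips P(s -> tip state)."""
        tree = Tree.from_newick("(A:0.1,B:0.2,C:0.3);")
        aln = Alignment.from_sequences({"A": "A", "B": "A", "C": "G"})
        anc = phylo_engine.marginal_ancestral_states(tree, aln, gtr_model)
        pi = np.array(gtr_model.base_freqs)
        Ps = {n.name: gtr_model.transition_probabilities(n.length) for n in tree.leaves()}
        joint = pi * Ps["A"][:, 0] * Ps["B"][:, 0] * Ps["C"][:, 2]
        expected = joint / joint.sum()
        assert np.allclose(anc.posteriors[tree.root.index][0], expected, atol=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_posteriors_normalised_everywhere(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(rng, 5)
        model = random_model(rng)
        aln = random_alignment(rng, tree.leaf_names(), 30)
        anc = phylo_engine.marginal_ancestral_states(tree, aln, model)
        for post in anc.posteriors.values():
            assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)


def _simulate_on_tree(tree, model, n_columns, rng):
    """Evolve sequences down a tree under the model (test helper)."""
    pi = np.array(model.base_freqs)
    states = {id(tree.root): rng.choice(4, size=n_columns, p=pi)}
    seqs = {}
    chars = np.array(list("ACGT"))
    for node in tree.preorder():
        if node is tree.root:
            continue
        P = model.transition_probabilities(node.length)
        parent = states[id(node.parent)]
        child = np.empty_like(parent)
        for s in range(4):
            mask = parent == s
            child[mask] = rng.choice(4, size=mask.sum(), p=P[s])
        states[id(node)] = child
        if node.is_leaf:
            seqs[node.name] = "".join(chars[child])
    return seqs
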