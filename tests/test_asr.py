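"""GTR likelihood and marginal reconstruction against enumeration oracles."""

import itertools

import numpy as np
import pytest

import opsinphylo as op
from opsinphylo import asr
from opsinphylo.asr import BASES, GtrModel, transition_matrix


def brute_force_loglik(tree, aln, model, branch_lengths):
    """Sum over all internal-state assignments, column by column."""
    eig = model.eig()
    pmats = {nid: transition_matrix(model, branch_lengths[nid], eig)
             for nid in branch_lengths}
    internal = [nid for nid in tree.postorder() if not tree.nodes[nid].is_leaf]
    tips = {nid: tree.nodes[nid].label for nid in tree.leaf_ids}
    pi = model.base_frequencies
    total = 0.0
    for col in range(aln.length):
        site = 0.0
        for assign in itertools.product(range(4), repeat=len(internal)):
            state = dict(zip(internal, assign))
            for nid, label in tips.items():
                c = aln[label][col]
                state[nid] = BASES.index(c) if c in BASES else None
            p = pi[state[tree.root_id]]
            for anc, desc in tree.branches():
                if state[desc] is None:  # gap: sum over states = 1
                    continue
                p *= pmats[desc][state[anc], state[desc]]
            site += p
        total += np.log(site)
    return total


def brute_force_posterior(tree, aln, model, branch_lengths, node, col):
    """Bayes posterior over the node's state by full enumeration."""
    eig = model.eig()
    pmats = {nid: transition_matrix(model, branch_lengths[nid], eig)
             for nid in branch_lengths}
    internal = [nid for nid in tree.postorder() if not tree.nodes[nid].is_leaf]
    tips = {nid: tree.nodes[nid].label for nid in tree.leaf_ids}
    pi = model.base_frequencies
    mass = np.zeros(4)
    for assign in itertools.product(range(4), repeat=len(internal)):
        state = dict(zip(internal, assign))
        for nid, label in tips.items():
            state[nid] = BASES.index(aln[label][col])
        p = pi[state[tree.root_id]]
        for anc, desc in tree.branches():
            p *= pmats[desc][state[anc], state[desc]]
        mass[state[node]] += p
    return mass / mass.sum()


def toy_model():
    return GtrModel(np.array([1.0, 2.0, 0.7, 1.3, 3.0, 1.0]),
                    np.array([0.3, 0.2, 0.3, 0.2]))


def random_alignment(taxa, length, rng, gap_rate=0.0):
    rows = {}
    for t in taxa:
        chars = [BASES[i] for i in rng.integers(0, 4, size=length)]
        if gap_rate:
            for i in range(length):
                if rng.random() < gap_rate:
                    chars[i] = "-"
        rows[t] = "".join(chars)
    return op.CodonAlignment(list(taxa), rows)


class TestPruningLikelihood:
    @pytest.mark.parametrize("newick,gaps", [
        ("((A:0.1,B:0.2)5:0.15,C:0.3)6;", 0.0),
        ("((A:0.1,B:0.2)6:0.15,(C:0.3,D:0.05)7:0.1)8;", 0.0),
        ("((A:0.1,B:0.2)6:0.15,(C:0.3,D:0.05)7:0.1)8;", 0.2),
        ("(((A:0.1,B:0.2)7:0.1,C:0.25)8:0.1,(D:0.3,E:0.05)9:0.1)10;", 0.0),
    ])
    def test_equals_enumeration(self, newick, gaps):
        tree = op.SpeciesTree.from_newick(newick)
        rng = np.random.default_rng(3)
        aln = random_alignment(sorted(tree.leaf_labels), 30, rng, gaps)
        model = toy_model()
        bl = {nid: tree.nodes[nid].edge_length for nid in tree.preorder()
              if nid != tree.root_id}
        got = asr.pruning_loglik(tree, aln, model, bl)
        want = brute_force_loglik(tree, aln, model, bl)
        assert got == pytest.approx(want, abs=1e-10)

    def test_label_permutation_invariance(self):
        tree = op.SpeciesTree.from_newick("((A:0.1,B:0.2)5:0.15,C:0.3)6;")
        rng = np.random.default_rng(4)
        aln = random_alignment(["A", "B", "C"], 40, rng)
        permuted = op.CodonAlignment(["C", "A", "B"], dict(aln.rows))
        model = toy_model()
        assert asr.pruning_loglik(tree, aln, model) == pytest.approx(
            asr.pruning_loglik(tree, permuted, model), abs=1e-12)


class TestFitGtr:
    def test_identical_sequences_zero_branches(self):
        tree = op.SpeciesTree.from_newick("(A:0.1,B:0.1)3;")
        aln = op.CodonAlignment(["A", "B"], {"A": "ACGT" * 25, "B": "ACGT" * 25})
        model, bl, info = op.fit_gtr(aln, tree)
        assert max(bl.values()) < 1e-6

    def test_jukes_cantor_distance_recovered(self):
        # JC-simulated pair: equal frequencies, equal exchangeabilities
        rng = np.random.default_rng(11)
        t_true = 0.3
        jc = GtrModel(np.ones(6), np.full(4, 0.25))
        p = transition_matrix(jc, t_true)
        n = 4000
        a_states = rng.integers(0, 4, size=n)
        b_states = np.array([rng.choice(4, p=p[i]) for i in a_states])
        aln = op.CodonAlignment(
            ["A", "B"],
            {"A": "".join(BASES[i] for i in a_states),
             "B": "".join(BASES[i] for i in b_states)})
        tree = op.SpeciesTree.from_newick("(A:0.1,B:0.1)3;")
        model, bl, info = op.fit_gtr(aln, tree)
        p_hat = np.mean(a_states != b_states)
        jc_distance = -0.75 * np.log(1 - 4.0 * p_hat / 3.0)
        assert sum(bl.values()) == pytest.approx(jc_distance, rel=0.05)
        # exchangeabilities statistically indistinguishable (all near equal)
        ratio = model.exchangeabilities.max() / model.exchangeabilities.min()
        assert ratio < 2.0

    def test_loglik_trace_monotone(self):
        tree = op.SpeciesTree.from_newick("((A:0.1,B:0.2)5:0.15,C:0.3)6;")
        rng = np.random.default_rng(5)
        aln = random_alignment(["A", "B", "C"], 60, rng)
        _, _, info = op.fit_gtr(aln, tree)
        trace = info["trace"]
        assert all(b >= a - 1e-6 for a, b in zip(trace, trace[1:]))


class TestMarginalReconstruct:
    def test_invariant_column_high_posterior(self):
        tree = op.SpeciesTree.from_newick(
            "((A:0.05,B:0.05)5:0.05,(C:0.05,D:0.05)6:0.05)7;")
        aln = op.CodonAlignment(["A", "B", "C", "D"],
                                {t: "A" * 20 for t in "ABCD"})
        model = toy_model()
        table = asr.marginal_reconstruct(aln, tree, model)
        for nid in (5, 6, 7):
            assert table.posteriors[nid][:, 0].min() > 0.99
            assert table.sequences[nid] == "A" * 20

    def test_posterior_equals_enumeration(self):
        tree = op.SpeciesTree.from_newick("((A:0.1,B:0.2)4:0.15,C:0.3)5;")
        rng = np.random.default_rng(6)
        aln = random_alignment(["A", "B", "C"], 12, rng)
        model = toy_model()
        bl = {nid: tree.nodes[nid].edge_length for nid in tree.preorder()
              if nid != tree.root_id}
        table = asr.marginal_reconstruct(aln, tree, model, bl)
        for node in (4, 5):
            for col in range(aln.length):
                want = brute_force_posterior(tree, aln, model, bl, node, col)
                got = table.posteriors[node][col]
                assert np.allclose(got, want, atol=1e-10), (node, col)

    def test_posteriors_sum_to_one_and_map_maximal(self):
        tree = op.SpeciesTree.from_newick("((A:0.1,B:0.2)4:0.15,C:0.3)5;")
        rng = np.random.default_rng(7)
        aln = random_alignment(["A", "B", "C"], 25, rng, gap_rate=0.1)
        model = toy_model()
        table = asr.marginal_reconstruct(aln, tree, model)
        for nid in (4, 5):
            post = table.posteriors[nid]
            assert np.allclose(post.sum(axis=1), 1.0, atol=1e-6)
            maps = [BASES[i] for i in post.argmax(axis=1)]
            assert "".join(maps) == table.sequences[nid]

    def test_tip_rows_are_observed_data(self, fixture_genes, tree):
        parts = fixture_genes["genes"]["RH1"]
        proj, _ = op.cds_projection(parts["alignment"], parts["model"])
        model = GtrModel(np.ones(6), np.full(4, 0.25))
        table = asr.marginal_reconstruct(proj, tree, model)
        label = "24_Tursiops_truncatus"
        nid = tree.id_of_label(label)
        assert table.sequences[nid] == proj[label]


class TestNodeResidues:
    def test_map_recovery_on_simulated_truth(self, pipeline_result,
                                             fixture_genes, tree):
        """MAP ancestral residues at the rod-opsin tuning sites match the
        simulation's true ancestral sequences at every internal node."""
        parts = fixture_genes["genes"]["RH1"]
        truth = parts["truth"]
        tuning = pipeline_result.genes["RH1"].tuning
        sites = (83, 292, 299)
        from opsinphylo.data_io import translate_codon
        for nid in tree.preorder():
            cds = truth.node_cds[nid]
            want = "".join(translate_codon(cds[(s - 1) * 3:(s - 1) * 3 + 3])
                           for s in sites)
            assert tuning.node_tuples[nid] == want, nid
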