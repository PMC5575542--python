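import numpy as np
import pytest

from helpers import brute_force_parsimony, enum_site_likelihood_and_posteriors
from paleoenrich.alphabet import AA_INDEX
from paleoenrich.asr import (
    AncestralReconstructionModel,
    AncestralReconstructionResults,
    fitch_indel_reconstruction,
)
from paleoenrich.containers import ProteinAlignment
from paleoenrich.simulate import SimulationConfig, evolve_alignment, gen_tree
from paleoenrich.substitution import build_model
from paleoenrich.trees import parse_newick


def _fit(aln, newick, model):
    return AncestralReconstructionModel(aln, parse_newick(newick), model).fit(
        optimize_branch_lengths=False
    )


class TestMarginalPosteriors:
    def test_identical_leaves_at_zero_distance_pin_the_ancestor(self, wag_g4):
        res = _fit(ProteinAlignment({"x": "K", "y": "K"}), "(x:0,y:0)A;", wag_g4)
        post = res.posteriors["A"]
        assert post[0, AA_INDEX["K"]] == pytest.approx(1.0, abs=1e-12)

    def test_columns_sum_to_one(self, wag_g4):
        cfg = SimulationConfig(n_leaves=6, seq_length=50, seed=13)
        tree = gen_tree(6, "yule", 0.2, 13)
        data = evolve_alignment(tree, cfg)
        res = AncestralReconstructionModel(data.alignment, data.tree, wag_g4).fit(
            optimize_branch_lengths=False
        )
        for node in res.node_names:
            sums = res.posteriors[node].sum(axis=1)
            assert np.abs(sums - 1).max() < 1e-8

    @pytest.mark.parametrize("newick,rows", [
        ("((t1:0.12,t2:0.3)U:0.2,t3:0.4)R;", {"t1": "AKC", "t2": "ARC", "t3": "GK-"}),
        ("(((a:0.1,b:0.25)U:0.15,c:0.3)V:0.1,d:0.5)R;",
         {"a": "AKW", "b": "GKW", "c": "GRC", "d": "G-C"}),
        ("((a:0.05,b:0.1)U:0.2,(c:0.3,d:0.4)V:0.1)R;",
         {"a": "DE", "b": "DE", "c": "EN", "d": "QN"}),
    ])
    def test_matches_enumeration_oracle(self, newick, rows, wag_g4):
        """Marginal posteriors at every internal node and site must equal the
        exhaustive sum over all ancestral state assignments."""
        aln = ProteinAlignment(rows)
        res = _fit(aln, newick, wag_g4)
        tree = parse_newick(newick)
        enc = {t: aln.encoded(t) for t in aln.taxa}
        for j in range(aln.length):
            site = {t: int(enc[t][j]) for t in aln.taxa}
            _, expected = enum_site_likelihood_and_posteriors(tree, wag_g4, site)
            for node, exp_post in expected.items():
                got = res.posteriors[node][j]
                assert np.abs(got - exp_post).max() < 1e-8


class TestMLSequence:
    def _fake_results(self, post, present=None):
        res = AncestralReconstructionResults.__new__(AncestralReconstructionResults)
        res.posteriors = {"n": np.asarray(post)}
        L = res.posteriors["n"].shape[0]
        res.presence = {"n": np.ones(L, bool) if present is None else np.asarray(present)}
        return res

    def test_argmax_state(self):
        col = np.zeros(20)
        col[AA_INDEX["A"]], col[AA_INDEX["R"]] = 0.7, 0.3
        assert self._fake_results([col]).ml_sequence("n") == "A"

    def test_tie_breaks_alphabetically(self):
        col = np.zeros(20)
        col[AA_INDEX["A"]] = col[AA_INDEX["R"]] = 0.5
        assert self._fake_results([col]).ml_sequence("n") == "A"
        col2 = np.zeros(20)
        col2[AA_INDEX["V"]] = col2[AA_INDEX["C"]] = 0.5
        assert self._fake_results([col2]).ml_sequence("n") == "C"

    def test_absent_site_emits_gap(self):
        col = np.zeros(20)
        col[AA_INDEX["W"]] = 1.0
        res = self._fake_results([col, col], present=[True, False])
        assert res.ml_sequence("n") == "W-"

    def test_ml_state_has_max_posterior(self, wag_g4):
        res = _fit(ProteinAlignment({"x": "AK", "y": "GK", "z": "AR"}),
                   "((x:0.2,y:0.3)U:0.1,z:0.4)R;", wag_g4)
        for node in res.node_names:
            states = res.ml_states(node)
            post = res.posteriors[node]
            assert np.allclose(post[np.arange(post.shape[0]), states],
                               post.max(axis=1))


class TestBinPosteriors:
    def _results_with_maxp(self, values):
        res = AncestralReconstructionResults.__new__(AncestralReconstructionResults)
        post = np.zeros((len(values), 20))
        post[:, 0] = values
        res.posteriors = {"n": post}
        res.presence = {"n": np.ones(len(values), bool)}
        return res

    def test_certain_sites_fill_top_bin(self):
        bins = self._results_with_maxp([1.0, 1.0, 1.0]).bin_posteriors("n")
        assert bins[-1] == pytest.approx(1.0)

    def test_hand_built_binning(self):
        bins = self._results_with_maxp([0.05, 0.55, 0.95]).bin_posteriors("n")
        expected = np.zeros(10)
        expected[[0, 5, 9]] = 1 / 3
        assert np.allclose(bins, expected)

    def test_proportions_sum_to_one(self, wag_g4):
        res = _fit(ProteinAlignment({"x": "AKCW", "y": "ARCW", "z": "GKC-"}),
                   "((x:0.2,y:0.3)U:0.1,z:0.4)R;", wag_g4)
        for node in res.node_names:
            assert res.bin_posteriors(node).sum() == pytest.approx(1.0, abs=1e-12)


class TestSampleAncestors:
    def test_degenerate_posterior_reproduces_ml_sequence(self, wag_g4):
        res = _fit(ProteinAlignment({"x": "KWC", "y": "KWC"}), "(x:0,y:0)A;", wag_g4)
        samples = res.sample_ancestors("A", n=5, seed=1)
        assert all(s == res.ml_sequence("A") for s in samples)

    def test_same_seed_identical_samples(self, wag_g4):
        res = _fit(ProteinAlignment({"x": "AKW", "y": "GRW", "z": "AK-"}),
                   "((x:0.3,y:0.4)U:0.2,z:0.3)R;", wag_g4)
        assert res.sample_ancestors("U", 5, seed=7) == res.sample_ancestors("U", 5, seed=7)
        assert res.sample_ancestors("U", 5, seed=7) != res.sample_ancestors("U", 5, seed=8)

    def test_sampling_frequencies_follow_posterior(self):
        res = AncestralReconstructionResults.__new__(AncestralReconstructionResults)
        post = np.zeros((1, 20))
        post[0, AA_INDEX["A"]] = post[0, AA_INDEX["V"]] = 0.5
        res.posteriors = {"n": post}
        res.presence = {"n": np.ones(1, bool)}
        n = 10_000
        draws = res.sample_ancestors("n", n=n, seed=3)
        frac_a = sum(s == "A" for s in draws) / n
        assert abs(frac_a - 0.5) < 3 * 0.5 / np.sqrt(n)


class TestFitch:
    def test_all_present_means_no_changes(self):
        tree = parse_newick("((A:1,B:1)X:1,(C:1,D:1)Y:1)R;")
        presence = {t: np.ones(3, bool) for t in "ABCD"}
        states, changes = fitch_indel_reconstruction(tree, presence)
        assert changes == 0
        assert all(states[n].all() for n in ("X", "Y", "R"))

    def test_single_absent_leaf_keeps_root_present(self):
        tree = parse_newick("((A:1,B:1)X:1,(C:1,D:1)Y:1)R;")
        presence = {t: np.array([t != "D"]) for t in "ABCD"}
        states, changes = fitch_indel_reconstruction(tree, presence)
        assert changes == 1
        assert states["R"][0] and states["X"][0] and states["Y"][0]

    def test_root_ambiguity_resolution_is_configurable(self):
        tree = parse_newick("(A:1,B:1)R;")
        presence = {"A": np.array([True]), "B": np.array([False])}
        present, _ = fitch_indel_reconstruction(tree, presence, root_ambiguous_present=True)
        absent, _ = fitch_indel_reconstruction(tree, presence, root_ambiguous_present=False)
        assert present["R"][0] and not absent["R"][0]

    def test_change_counts_match_brute_force_on_random_patterns(self, rng):
        tree = parse_newick(
            "(((A:1,B:1)N1:1,(C:1,D:1)N2:1)N3:1,(E:1,F:1)N4:1)R;"
        )
        for _ in range(100):
            pattern = rng.random(6) < 0.5
            presence = {t: np.array([p]) for t, p in zip("ABCDEF", pattern)}
            _, changes = fitch_indel_reconstruction(tree, presence)
            expected = brute_force_parsimony(tree, dict(zip("ABCDEF", pattern)))
            assert changes == expected


class TestBranchSupport:
    def test_no_signal_gives_alr_near_one(self, wag_g4):
        tree = parse_newick("((A:1e-8,B:1e-8)X:1e-8,(C:1e-8,D:1e-8)Y:1e-8)R;")
        cfg = SimulationConfig(n_leaves=4, seq_length=100, seed=6,
                               indel_column_fraction=0.0)
        data = evolve_alignment(tree, cfg)
        model = build_model("WAG", 1.0, 2)
        bs = AncestralReconstructionModel(data.alignment, data.tree, model).branch_support("X")
        assert bs.aLR == pytest.approx(1.0, abs=0.05)
        assert np.isfinite(bs.log10_aLR)

    def test_strong_clade_support_exceeds_one(self, wag_g4):
        tree = parse_newick("((A:0.1,B:0.1)X:0.5,(C:0.1,D:0.1)Y:0.5)R;")
        cfg = SimulationConfig(n_leaves=4, seq_length=300, seed=11,
                               indel_column_fraction=0.0)
        data = evolve_alignment(tree, cfg)
        model = build_model("WAG", 1.0, 2)
        bs = AncestralReconstructionModel(data.alignment, data.tree, model).branch_support("X")
        assert bs.aLR > 1.0
        assert bs.log10_aLR > 1.0
        assert np.isfinite(bs.log10_aLR)

    def test_pendant_branch_rejected(self, wag_g4):
        aln = ProteinAlignment({"A": "AK", "B": "AK", "C": "GK"})
        tree = parse_newick("((A:0.1,B:0.1)X:0.1,C:0.1)R;")
        arm = AncestralReconstructionModel(aln, tree, wag_g4)
        with pytest.raises(ValueError):
            arm.branch_support("X")  # sibling C is a leaf: pendant unrooted edge


class TestReconstructionAccuracy:
    def test_identity_to_truth_improves_as_branches_shrink(self):
        """ML ancestors converge to the true ancestors as divergence drops."""
        model = build_model("WAG", 1.0, 2)
        base = gen_tree(6, "yule", 0.4, 21)
        identities = []
        for scale in (1.0, 0.5, 0.1, 0.01):
            tree = base.clone(depth=1)
            for node in tree.preorder_node_iter():
                if node.parent_node is not None:
                    node.edge.length *= scale
            cfg = SimulationConfig(n_leaves=6, seq_length=300, seed=31,
                                   n_rate_categories=2, indel_column_fraction=0.0)
            data = evolve_alignment(tree, cfg)
            res = AncestralReconstructionModel(data.alignment, data.tree, model).fit(
                optimize_branch_lengths=False
            )
            site_ident = []
            for node in res.node_names:
                truth = data.true_sequence(node, gapped=False)
                ml = res.ml_sequence(node)
                site_ident.append(np.mean([x == y for x, y in zip(ml, truth)]))
            identities.append(float(np.mean(site_ident)))
        assert identities == sorted(identities)
        assert identities[-1] > 0.995


class TestResultsReporting:
    def test_summary_and_node_tables(self, wag_g4, tmp_path):
        res = _fit(ProteinAlignment({"x": "AKW", "y": "ARW", "z": "GK-"}),
                   "((x:0.2,y:0.3)U:0.1,z:0.4)R;", wag_g4)
        text = res.summary()
        assert "log-likelihood" in text and "U" in text
        table = res.node_table("U")
        assert list(table["site"]) == [1, 2, 3]
        assert np.allclose(table.filter(like="p_").sum(axis=1), 1.0, atol=1e-6)
        written = res.to_directory(tmp_path)
        assert any(p.name == "posterior_bins.tsv" for p in written)
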