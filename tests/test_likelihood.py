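import numpy as np
import pytest

from bustedmh.likelihood import (
    AlignmentError,
    CodonAlignment,
    LikelihoodEngine,
    ModelParameters,
    PhyloTree,
    TreeError,
    mixture_transition_matrix,
)
from bustedmh.rates import (
    AlphaGrid,
    MHRates,
    NucleotideBias,
    OmegaGrid,
    PositionalFrequencies,
    stationary_distribution,
)
from bustedmh.simulate import four_taxon_tree

from oracles import brute_force_loglik

PAIRS = ("AC", "AG", "AT", "CG", "CT", "GT")


def random_model_parameters(rng, tree, K=2, L=2, mh=True):
    theta = NucleotideBias({p: (1.0 if p == "AG" else float(rng.uniform(0.3, 2)))
                            for p in PAIRS})
    pi = PositionalFrequencies(rng.dirichlet([10] * 4, size=3))
    sub = np.sort(rng.uniform(0.05, 1.0, size=K - 1))
    omegas = np.concatenate([sub, [float(rng.uniform(1.0, 5.0))]])
    ow = rng.dirichlet([5] * K)
    alphas_raw = np.sort(rng.uniform(0.3, 3.0, size=L))
    aw = rng.dirichlet([5] * L)
    bl = np.zeros(tree.n_nodes)
    bl[tree.branch_ids] = rng.uniform(0.02, 0.5, size=len(tree.branch_ids))
    return ModelParameters(
        theta=theta, pi=pi,
        omega_grid=OmegaGrid(omegas, ow),
        alpha_grid=AlphaGrid.from_raw(alphas_raw, aw),
        mh=MHRates(float(rng.uniform(0, 0.8)), float(rng.uniform(0, 0.8)))
        if mh else MHRates(),
        branch_lengths=bl)


def random_alignment(rng, code, n_sites, names=("a", "b", "c", "d")):
    seqs = {n: "".join(code.sense_codons[rng.integers(61)]
                       for _ in range(n_sites)) for n in names}
    return CodonAlignment(seqs, code=code)


# ---------------------------------------------------------------------------
# tree & alignment plumbing
# ---------------------------------------------------------------------------

class TestPhyloTree:
    def test_four_taxon_unrooted_branch_count(self):
        tree = PhyloTree.from_newick(
            "((a:0.1,b:0.1):0.05,(c:0.2,d:0.2):0.05);")
        assert tree.n_leaves == 4
        assert tree.n_branches == 5  # bifurcating root collapsed

    def test_duplicate_leaf_labels_rejected(self):
        with pytest.raises(TreeError):
            PhyloTree.from_newick("((a:0.1,a:0.1):0.1,b:0.1,c:0.1);")

    def test_zero_length_branches_accepted(self):
        tree = PhyloTree.from_newick("((a:0.0,b:0.1):0.0,c:0.1,d:0.1);")
        assert tree.branch_lengths.min() == 0.0

    def test_newick_round_trip(self):
        tree = four_taxon_tree(0.2)
        again = PhyloTree.from_newick(tree.to_newick())
        assert sorted(again.leaf_names) == sorted(tree.leaf_names)
        assert again.n_branches == tree.n_branches
        assert again.branch_lengths.sum() == pytest.approx(
            tree.branch_lengths.sum())


class TestCodonAlignment:
    def test_identical_codons_single_pattern(self, code):
        aln = CodonAlignment({n: "ACTACTACT" for n in "abcd"})
        assert aln.n_sites == 3
        assert aln.n_patterns == 1
        assert aln.pattern_counts.sum() == 3

    def test_length_validation(self):
        with pytest.raises(AlignmentError):
            CodonAlignment({"a": "ACTG", "b": "ACTG"})
        with pytest.raises(AlignmentError):
            CodonAlignment({"a": "ACT", "b": "ACTACT"})

    def test_stop_codon_rejected_with_location(self):
        with pytest.raises(AlignmentError, match=r"TAA.*'b'.*codon 2"):
            CodonAlignment({"a": "ACTACT", "b": "ACTTAA"})

    def test_stop_codon_maskable(self):
        aln = CodonAlignment({"a": "ACTACT", "b": "ACTTAA"}, mask_stops=True)
        exact, partial = aln.leaf_partial(1)
        # masked codon becomes fully missing
        assert partial is not None

    def test_ambiguous_codon_partial_state(self, code):
        aln = CodonAlignment({"a": "ACTNNN", "b": "ACTACT"})
        si = aln.names.index("a")
        state = aln.states[si, 1]
        assert state < 0
        assert aln.ambiguity_masks[-1 - state].sum() == 61


# ---------------------------------------------------------------------------
# transition matrices
# ---------------------------------------------------------------------------

class TestMixtureTransitionMatrix:
    theta = NucleotideBias.hky(2.0)
    pi = PositionalFrequencies.equal()
    grid = OmegaGrid([0.1, 0.5, 2.0], [0.5, 0.3, 0.2])

    def test_zero_time_is_identity(self):
        M = mixture_transition_matrix(self.theta, self.pi, self.grid,
                                      alpha=1.0, t=0.0)
        np.testing.assert_allclose(M, np.eye(61), atol=1e-12)

    def test_single_category_is_plain_exponential(self):
        from scipy.linalg import expm
        from bustedmh.rates import build_rate_matrix
        g1 = OmegaGrid([0.7], [1.0])
        rm = build_rate_matrix(self.theta, self.pi, 0.7)
        M = mixture_transition_matrix(self.theta, self.pi, g1, 1.0, 0.3)
        np.testing.assert_allclose(
            M, expm(rm.q * (3 * 0.3 / rm.scale)), atol=1e-10)

    @pytest.mark.parametrize("t", [0.01, 0.1, 1.0])
    def test_rows_sum_to_one(self, rng, t):
        M = mixture_transition_matrix(self.theta, self.pi, self.grid,
                                      alpha=float(rng.uniform(0.3, 2)), t=t,
                                      mh=MHRates(0.3, 0.2))
        np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)
        assert M.min() >= -1e-14

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            mixture_transition_matrix(self.theta, self.pi, self.grid, 1.0,
                                      -0.1)


# ---------------------------------------------------------------------------
# pruning engine
# ---------------------------------------------------------------------------

class TestLogLikelihood:
    def test_identical_sequences_zero_branches(self, code):
        """Two identical 1-codon sequences on zero-length branches:
        P(D) is the stationary probability of that codon."""
        tree = PhyloTree.from_newick("(a:0.0,b:0.0);")
        aln = CodonAlignment({"a": "ACT", "b": "ACT"})
        rng = np.random.default_rng(0)
        params = random_model_parameters(rng, tree)
        params.branch_lengths[:] = 0.0
        table = LikelihoodEngine(aln, tree).log_likelihood(params)
        statd = stationary_distribution(params.pi, code)
        expected = statd[code.codon_index["ACT"]]
        assert np.exp(table.lnl) == pytest.approx(expected, rel=1e-10)

    def test_matches_exhaustive_enumeration(self, code):
        """Pruning equals brute-force summation over internal states and
        all branch-site omega / site alpha assignments (random instances)."""
        rng = np.random.default_rng(42)
        for _ in range(5):
            tree = four_taxon_tree(0.1)
            params = random_model_parameters(rng, tree, K=2, L=2)
            tree.branch_lengths[:] = params.branch_lengths
            aln = random_alignment(rng, code, n_sites=2)
            fast = LikelihoodEngine(aln, tree).log_likelihood(params).lnl
            slow = brute_force_loglik(
                aln, tree, code.sense_codons,
                {c: code.codon_to_aa[c] for c in code.sense_codons},
                params.theta.theta, params.pi.pi,
                (params.omega_grid.omegas, params.omega_grid.weights),
                (params.alpha_grid.alphas, params.alpha_grid.weights),
                params.mh.delta, params.mh.psi)
            assert fast == pytest.approx(slow, rel=1e-10)

    def test_unit_alpha_grid_collapses_to_no_srv(self, code, rng):
        tree = four_taxon_tree(0.2)
        aln = random_alignment(rng, code, n_sites=20)
        params = random_model_parameters(rng, tree, L=3)
        engine = LikelihoodEngine(aln, tree)
        params_unit = ModelParameters(
            theta=params.theta, pi=params.pi, omega_grid=params.omega_grid,
            alpha_grid=AlphaGrid(np.ones(3), np.full(3, 1 / 3)),
            mh=params.mh, branch_lengths=params.branch_lengths)
        params_nosrv = ModelParameters(
            theta=params.theta, pi=params.pi, omega_grid=params.omega_grid,
            alpha_grid=AlphaGrid.constant(1),
            mh=params.mh, branch_lengths=params.branch_lengths)
        l1 = engine.log_likelihood(params_unit).lnl
        l2 = engine.log_likelihood(params_nosrv).lnl
        assert l1 == pytest.approx(l2, rel=1e-12)

    def test_pattern_compression_invariance(self, code, rng):
        """Repeating columns scales their log-likelihood contribution."""
        tree = four_taxon_tree(0.15)
        aln1 = random_alignment(rng, code, n_sites=6)
        seqs = {n: aln1.sequence_string(n) * 3 for n in aln1.names}
        aln3 = CodonAlignment(seqs, code=code)
        assert aln3.n_patterns == aln1.n_patterns
        params = random_model_parameters(np.random.default_rng(9), tree)
        tree.branch_lengths[:] = params.branch_lengths
        l1 = LikelihoodEngine(aln1, tree).log_likelihood(params).lnl
        l3 = LikelihoodEngine(aln3, tree).log_likelihood(params).lnl
        assert l3 == pytest.approx(3 * l1, rel=1e-12)

    def test_all_gap_column_likelihood_one(self, code):
        tree = four_taxon_tree(0.2)
        aln = CodonAlignment({n: "ACT---" for n in "abcd"})
        params = random_model_parameters(np.random.default_rng(2), tree)
        tree.branch_lengths[:] = params.branch_lengths
        table = LikelihoodEngine(aln, tree).log_likelihood(params)
        gap_site = table.log_site[1]
        assert gap_site == pytest.approx(0.0, abs=1e-10)

    def test_root_placement_invariance(self, code, rng):
        """Under reversibility the likelihood does not depend on where the
        (arbitrary) root is placed."""
        import dendropy
        newick1 = "((a:0.1,b:0.2):0.15,c:0.25,d:0.1);"
        aln = random_alignment(rng, code, n_sites=15)
        t1 = PhyloTree.from_newick(newick1)
        d2 = dendropy.Tree.get(data=newick1, schema="newick")
        d2.reroot_at_edge(d2.find_node_with_taxon_label("c").edge,
                          length1=0.1, length2=0.15,
                          update_bipartitions=False)
        t2 = PhyloTree.from_dendropy(d2)
        params1 = random_model_parameters(np.random.default_rng(5), t1)
        params1.branch_lengths[:] = t1.branch_lengths
        params2 = ModelParameters(
            theta=params1.theta, pi=params1.pi,
            omega_grid=params1.omega_grid, alpha_grid=params1.alpha_grid,
            mh=params1.mh, branch_lengths=t2.branch_lengths.copy())
        l1 = LikelihoodEngine(aln, t1).log_likelihood(params1).lnl
        l2 = LikelihoodEngine(aln, t2).log_likelihood(params2).lnl
        assert l1 == pytest.approx(l2, rel=1e-9)

    def test_label_mismatch_rejected(self, code, rng):
        tree = four_taxon_tree(0.2)
        aln = random_alignment(rng, code, 4, names=("a", "b", "c", "x"))
        with pytest.raises(TreeError, match="x"):
            LikelihoodEngine(aln, tree)

    def test_site_table_bookkeeping(self, code, rng):
        tree = four_taxon_tree(0.2)
        aln = random_alignment(rng, code, n_sites=30)
        params = random_model_parameters(rng, tree, K=3, L=3)
        tree.branch_lengths[:] = params.branch_lengths
        table = LikelihoodEngine(aln, tree).log_likelihood(params)
        assert table.lnl == pytest.approx(table.log_site.sum(), rel=1e-12)
        assert np.all(table.site_likelihoods <= 1.0 + 1e-12)
        assert np.all(table.site_likelihoods > 0.0)
        # mixture over alpha categories reproduces the site likelihood
        w = params.alpha_grid.weights
        mixed = np.log(np.exp(table.log_site_by_alpha).T @ w)
        np.testing.assert_allclose(mixed, table.log_site, rtol=1e-10)
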