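from types import SimpleNamespace

import numpy as np
import pytest

from bustedmh.diagnostics import (
    branch_site_ebf,
    lrt_site_profile,
    site_evidence_ratios,
)
from bustedmh.inference import fit_eds_pair
from bustedmh.likelihood import (
    CodonAlignment,
    LikelihoodEngine,
    ModelParameters,
    PhyloTree,
)
from bustedmh.model import BustedModel
from bustedmh.rates import (
    AlphaGrid,
    MHRates,
    ModelConfig,
    NucleotideBias,
    OmegaGrid,
    PositionalFrequencies,
    build_rate_matrix,
    stationary_distribution,
)


def _fake_results(log_site):
    table = SimpleNamespace(log_site=np.asarray(log_site, dtype=float))
    return SimpleNamespace(site_table=table)


class TestEvidenceRatios:
    def test_identical_fits_give_unit_ratios(self):
        r = _fake_results([-3.0, -1.5, -7.0])
        np.testing.assert_allclose(site_evidence_ratios(r, r), 1.0)

    def test_log_ratios_sum_to_loglik_difference(self, small_fit_pair):
        alt, null = small_fit_pair
        er = site_evidence_ratios(alt, null)
        assert np.log(er).sum() == pytest.approx(alt.llf - null.llf,
                                                 abs=1e-8)

    def test_site_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            site_evidence_ratios(_fake_results([-1.0]),
                                 _fake_results([-1.0, -2.0]))


class TestSiteProfile:
    def test_equal_contributions_arithmetic(self):
        """Ten equally contributing sites: 8 are needed for an 80% share."""
        alt = _fake_results(np.full(10, -2.0))
        null = _fake_results(np.full(10, -2.5))
        prof = lrt_site_profile(alt, null)
        assert prof.total_lrt == pytest.approx(10.0)
        assert prof.n_sites_for_share == 8

    def test_single_site_signal(self):
        logs = np.full(30, -2.0)
        alt_logs = logs.copy()
        alt_logs[7] += 6.0  # one site carries everything
        prof = lrt_site_profile(_fake_results(alt_logs), _fake_results(logs))
        assert prof.n_sites_for_share == 1
        assert prof.order[0] == 7

    def test_nonpositive_total_reports_zero_sites(self):
        alt = _fake_results([-2.0, -2.0])
        null = _fake_results([-1.0, -1.0])
        prof = lrt_site_profile(alt, null)
        assert prof.total_lrt < 0
        assert prof.n_sites_for_share == 0

    def test_contributions_sum_to_lrt(self, small_fit_pair):
        alt, null = small_fit_pair
        prof = lrt_site_profile(alt, null)
        assert prof.contributions.sum() == pytest.approx(
            2.0 * (alt.llf - null.llf), abs=1e-8)
        assert "site\t" in prof.to_table()


class TestBranchSiteEbf:
    def _two_taxon_setup(self):
        tree = PhyloTree.from_newick("(a:0.3,b:0.2);")
        aln = CodonAlignment({"a": "ATGAAA", "b": "ATGCGC"})
        rng = np.random.default_rng(8)
        params = ModelParameters(
            theta=NucleotideBias.hky(2.0),
            pi=PositionalFrequencies(rng.dirichlet([12] * 4, size=3)),
            omega_grid=OmegaGrid([0.1, 0.6, 3.0], [0.6, 0.3, 0.1]),
            alpha_grid=AlphaGrid.from_raw([0.5, 1.7], [0.5, 0.5]),
            mh=MHRates(0.2, 0.1),
            branch_lengths=tree.branch_lengths.copy())
        return tree, aln, params

    def test_matches_direct_bayes_computation(self, code):
        """EBF on a 2-taxon toy equals the hand-rolled posterior built from
        explicit matrix exponentials."""
        from scipy.linalg import expm
        tree, aln, params = self._two_taxon_setup()
        engine = LikelihoodEngine(aln, tree)
        fit = SimpleNamespace(model=SimpleNamespace(engine=engine, tree=tree),
                              params=params,
                              p3=params.omega_grid.weights[-1],
                              site_table=engine.log_likelihood(params))
        support = branch_site_ebf(fit)

        statd = stationary_distribution(params.pi, code)
        qs, scales = [], []
        for om in params.omega_grid.omegas:
            rm = build_rate_matrix(params.theta, params.pi, om, params.mh,
                                   code)
            qs.append(rm.q)
            scales.append(rm.scale)
        C = float(params.omega_grid.weights @ np.array(scales))

        def site_lik(site, collapse_branch=None):
            total = 0.0
            sa = aln.states[aln.names.index("a"), site]
            sb = aln.states[aln.names.index("b"), site]
            for al, fw in zip(params.alpha_grid.alphas,
                              params.alpha_grid.weights):
                mats = {}
                for b, name in zip(range(2), ("a", "b")):
                    leaf = tree.leaf_ids[name]
                    t = 3.0 * al * params.branch_lengths[leaf] / C
                    if collapse_branch == leaf:
                        M = expm(qs[-1] * t)
                    else:
                        M = sum(w * expm(q * t) for w, q in
                                zip(params.omega_grid.weights, qs))
                    mats[leaf] = M
                la = mats[tree.leaf_ids["a"]][:, sa]
                lb = mats[tree.leaf_ids["b"]][:, sb]
                total += fw * float(statd @ (la * lb))
            return total

        prior = params.omega_grid.weights[-1]
        for row, b in enumerate(tree.branch_ids):
            for s in range(aln.n_sites):
                post = site_lik(s, collapse_branch=int(b)) * prior / site_lik(s)
                ebf = (post / (1 - post)) / (prior / (1 - prior))
                assert support.posterior[row, s] == pytest.approx(
                    post, rel=1e-10)
                assert support.ebf[row, s] == pytest.approx(ebf, rel=1e-10)

    def test_uninformative_site_has_unit_ebf(self, code):
        """Identical codons across taxa on near-zero branches leave the
        posterior at the prior."""
        tree = PhyloTree.from_newick("(a:1e-8,b:1e-8);")
        aln = CodonAlignment({"a": "ATG", "b": "ATG"})
        _, _, params = self._two_taxon_setup()
        params = ModelParameters(
            theta=params.theta, pi=params.pi, omega_grid=params.omega_grid,
            alpha_grid=params.alpha_grid, mh=params.mh,
            branch_lengths=tree.branch_lengths.copy())
        engine = LikelihoodEngine(aln, tree)
        fit = SimpleNamespace(model=SimpleNamespace(engine=engine, tree=tree),
                              params=params,
                              p3=params.omega_grid.weights[-1],
                              site_table=engine.log_likelihood(params))
        support = branch_site_ebf(fit)
        np.testing.assert_allclose(support.ebf, 1.0, atol=1e-4)

    def test_no_selective_class_marker(self):
        tree, aln, params = self._two_taxon_setup()
        engine = LikelihoodEngine(aln, tree)
        fit = SimpleNamespace(model=SimpleNamespace(engine=engine, tree=tree),
                              params=params, p3=0.0,
                              site_table=engine.log_likelihood(params))
        support = branch_site_ebf(fit)
        assert support.no_selective_class
        assert support.pairs_above(100.0) == 0

    def test_few_extreme_ebfs_without_selection(self, small_fit_pair):
        """On data simulated without positive selection, EBF > 100 should be
        rare (under 1% of branch-site pairs)."""
        alt, _ = small_fit_pair
        support = branch_site_ebf(alt)
        frac = support.pairs_above(100.0) / support.ebf.size
        assert frac < 0.01


def test_branch_value_figure_export(tmp_path):
    import matplotlib
    matplotlib.use("Agg")
    from bustedmh.diagnostics import plot_branch_values
    from bustedmh.simulate import four_taxon_tree
    tree = four_taxon_tree(0.2)
    vals = {tree.branch_name(b): float(i + 1)
            for i, b in enumerate(tree.branch_ids)}
    out = tmp_path / "branches.svg"
    plot_branch_values(tree, vals, path=out)
    assert out.stat().st_size > 0


class TestSingleSiteScenario:
    """One codon carrying a triple-nucleotide substitution on a short
    terminal branch — the single-codon scenario where support for the
    multihit model concentrates at one site, and masking that codon removes
    it."""

    @staticmethod
    def _sim_with_mh_site(seed, n_bg=99, bl=0.1):
        from bustedmh.simulate import SimulationSpec, four_taxon_tree, \
            simulate_alignment
        tree = four_taxon_tree(bl)
        spec = SimulationSpec(tree=tree, n_codons=n_bg,
                              omega_grid=OmegaGrid([0.1], [1.0]),
                              alpha_grid=AlphaGrid.constant(1), seed=seed)
        a = simulate_alignment(spec).alignment
        # conserved CAG column with one instantaneous CAG->GCA (Q->A) change
        seqs = {n: a.sequence_string(n) + ("GCA" if n == "a" else "CAG")
                for n in a.names}
        return CodonAlignment(seqs), tree

    @staticmethod
    def _fit_s_and_smh(aln, tree, seed):
        mS = BustedModel(aln, tree, config=ModelConfig.s())
        fS = mS.fit(starts=1, seed=seed, effort=0.4, warn_overfit=False)
        mMH = BustedModel(aln, tree, config=ModelConfig.smh())
        mMH._nuc_stage = (fS.params.theta,
                          fS.params.branch_lengths.copy())
        fMH = mMH.fit(start_params=fS, starts=1, seed=seed, effort=0.4,
                      warn_overfit=False)
        return fS, fMH

    def test_evidence_ratio_localizes_mh_site(self):
        """The +S+MH / +S evidence ratio is maximal at the codon carrying
        the multinucleotide substitution, replicate after replicate."""
        hits = 0
        n_reps = 5
        for rep in range(n_reps):
            aln, tree = self._sim_with_mh_site(500 + rep)
            fS, fMH = self._fit_s_and_smh(aln, tree, rep)
            er = site_evidence_ratios(fMH, fS)
            if er.argmax() == aln.n_sites - 1:
                hits += 1
        assert hits >= n_reps - 1

    def test_masking_mh_codon_removes_multihit_signal(self):
        """Replacing the driving codon with gaps cannot increase the
        +S vs +S+MH likelihood-ratio statistic (the masking experiment)."""
        aln, tree = self._sim_with_mh_site(500)
        fS, fMH = self._fit_s_and_smh(aln, tree, 0)
        lrt_full = max(2.0 * (fMH.llf - fS.llf), 0.0)
        assert lrt_full > 0.1  # the single codon creates real MH support
        seqs = {n: aln.sequence_string(n)[:-3] + "NNN" for n in aln.names}
        masked = CodonAlignment(seqs)
        fS2, fMH2 = self._fit_s_and_smh(masked, tree, 0)
        lrt_masked = max(2.0 * (fMH2.llf - fS2.llf), 0.0)
        assert lrt_masked <= lrt_full + 0.1
        assert fMH2.params.mh.psi <= fMH.params.mh.psi + 0.05
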