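"""Site-class model fits, LRTs, and BEB."""

import numpy as np
import pytest
from scipy import stats as sps

from codonsel.alignment import CodonAlignment
from codonsel.errors import ContentError, UsageError
from codonsel.genetics import STANDARD_CODE
from codonsel.likelihood import site_likelihoods
from codonsel.ratematrix import estimate_frequencies
from codonsel.sitemodels import (
    FitConfig,
    ModelFit,
    beb_sites,
    chi2_tail,
    discretize_beta,
    dist_m7,
    dist_m8,
    fit_model,
    lrt,
    naive_eb_positive,
)
from codonsel.simulate import SimulationSpec, simulate_alignment
from codonsel.trees import PhyloTree

from conftest import fast_config


class TestDiscretization:
    def test_beta_bin_medians_match_scipy(self):
        om = discretize_beta(0.7, 2.3, K=10)
        expected = sps.beta.ppf((2 * np.arange(10) + 1) / 20, 0.7, 2.3)
        np.testing.assert_allclose(om, expected, atol=1e-9)
        assert np.all((om > 0) & (om < 1))

    def test_m7_m8_class_structure(self):
        d7 = dist_m7(0.5, 2.0, K=10)
        assert d7.K == 10
        np.testing.assert_allclose(d7.weights, 0.1)
        d8 = dist_m8(0.9, 0.5, 2.0, 3.5, K=10)
        assert d8.K == 11
        assert d8.omegas[-1] == 3.5
        assert d8.weights[-1] == pytest.approx(0.1)
        np.testing.assert_allclose(d8.weights[:10], 0.09)


class TestM0:
    def test_recovers_simulated_omega(self):
        """Simulator-as-oracle: M0 truth omega=0.2, 16 taxa x 500 codons."""
        from codonsel.sitemodels import dist_m0

        spec = SimulationSpec(
            site_classes=dist_m0(0.2), n_sites=500, seed=13, n_taxa=16, total_length=2.0
        )
        aln, _, tree = simulate_alignment(spec)
        fit = fit_model(aln, tree, "M0", "F3X4", fast_config())
        assert 0.15 <= fit.params["omega"] <= 0.25

    def test_degenerate_alignment_rejected(self):
        i = STANDARD_CODE.index("ATG")
        aln = CodonAlignment(
            taxa=["a", "b", "c"],
            codons=np.full((3, 10), i, dtype=np.int16),
            reference_taxon="a",
        )
        tree = PhyloTree.from_newick_string("(a:0.1,b:0.1,c:0.1);")
        with pytest.raises(ContentError):
            fit_model(aln, tree, "M0", "F3X4", fast_config())


class TestNesting:
    def test_m8_with_p0_one_reduces_to_m7(self, m2a_sim):
        aln, _, tree = m2a_sim
        freq = estimate_frequencies(aln, "F3X4")
        d7 = dist_m7(0.4, 1.5)
        d8 = dist_m8(1.0, 0.4, 1.5, 7.0)
        lnL7 = site_likelihoods(aln, tree, 2.0, freq, d7).lnL
        lnL8 = site_likelihoods(aln, tree, 2.0, freq, d8).lnL
        assert lnL8 == pytest.approx(lnL7, abs=1e-9)

    def test_alternative_never_below_null(self, m2a_fits):
        assert m2a_fits["M2a"].lnL >= m2a_fits["M1a"].lnL - 1e-9
        assert m2a_fits["M8"].lnL >= m2a_fits["M7"].lnL - 1e-9

    def test_m2a_on_null_data_collapses(self, m1a_sim, fast_cfg):
        """M2a fitted to M1a-simulated data: selection weight ~0, LRT stat ~0."""
        aln, _, tree = m1a_sim
        m0 = fit_model(aln, tree, "M0", "F3X4", fast_cfg)
        m1a = fit_model(aln, tree, "M1a", "F3X4", fast_cfg, m0_fit=m0)
        m2a = fit_model(aln, tree, "M2a", "F3X4", fast_cfg, m0_fit=m0, null_fit=m1a)
        res = lrt(m1a, m2a)
        p2 = 1.0 - m2a.params["p0"] - m2a.params["p1"]
        assert res.stat < 1.0
        assert p2 < 0.05 or res.stat < 0.5

    def test_selection_detected_on_selected_data(self, m2a_fits):
        res = lrt(m2a_fits["M1a"], m2a_fits["M2a"])
        assert res.p_value < 1e-6
        assert 3.0 <= m2a_fits["M2a"].params["omega2"] <= 8.0


class TestLRT:
    def test_zero_stat_gives_p_one(self, m2a_fits):
        from dataclasses import replace

        m1a = m2a_fits["M1a"]
        # an M2a whose parameters embed the fitted M1a exactly: same lnL
        embedded = replace(
            m1a, model="M2a", n_free_params=4,
            params={"p0": m1a.params["p0"], "p1": 1 - m1a.params["p0"],
                    "omega0": m1a.params["omega0"], "omega2": 1.0},
        )
        res = lrt(m1a, embedded)
        assert res.stat == 0.0 and res.p_value == 1.0

    def test_df_two_closed_form(self):
        assert chi2_tail(10.0, 2) == pytest.approx(np.exp(-5.0))
        assert chi2_tail(10.0, 2) == pytest.approx(sps.chi2.sf(10.0, 2), rel=1e-12)

    def test_mismatched_frequency_models_rejected(self, m2a_sim, m2a_fits, fast_cfg):
        aln, _, tree = m2a_sim
        other = fit_model(
            aln, tree, "M1a", "F61", fast_cfg, m0_fit=None
        )
        with pytest.raises(UsageError):
            lrt(other, m2a_fits["M2a"])

    def test_non_nested_pair_rejected(self, m2a_fits):
        with pytest.raises(UsageError):
            lrt(m2a_fits["M7"], m2a_fits["M2a"])


class TestBEB:
    def test_degenerate_grid_equals_neb(self, m2a_sim, m2a_fits, fast_cfg):
        """A single grid point at the MLE reduces BEB to the NEB posterior."""
        aln, _, tree = m2a_sim
        m2a = m2a_fits["M2a"]
        p = m2a.params
        grids = {
            "p0": np.array([p["p0"]]),
            "r": np.array([p["p1"] / (1 - p["p0"])]),
            "omega0": np.array([p["omega0"]]),
            "omega2": np.array([p["omega2"]]),
        }
        beb = beb_sites(aln, tree, m2a, fast_cfg, grids=grids)
        tree_hat = tree.with_lengths(m2a.branch_lengths)
        res = site_likelihoods(aln, tree_hat, m2a.kappa_hat, m2a.freq, m2a.dist)
        np.testing.assert_allclose(beb.post_positive, naive_eb_positive(res), atol=1e-8)

    def test_detects_simulated_selection(self, m2a_sim, m2a_fits, true_positive_sites, fast_cfg):
        aln, _, tree = m2a_sim
        beb = beb_sites(aln, tree, m2a_fits["M8"], fast_cfg)
        hits = set(int(i) for i in beb.selected_sites)
        true = true_positive_sites
        neutral = set(range(aln.n_sites)) - true
        assert len(hits & true) >= len(true) * 0.4
        assert len(hits & neutral) <= max(2, 0.05 * len(neutral))

    def test_invariant_alignment_flags_nothing(self):
        """No substitutions -> no site can reach the 0.90 posterior cutoff."""
        i = STANDARD_CODE.index("GCT")
        aln = CodonAlignment(
            taxa=["a", "b", "c", "d"],
            codons=np.full((4, 30), i, dtype=np.int16),
            reference_taxon="a",
        )
        tree = PhyloTree.from_newick_string("(a:0.2,b:0.2,(c:0.2,d:0.2):0.1);")
        freq = estimate_frequencies(aln, "F3X4")
        fit = ModelFit(
            model="M2a", freq_kind="F3X4", kappa_hat=2.0,
            params={"p0": 0.6, "p1": 0.3, "omega0": 0.1, "omega2": 4.0},
            branch_lengths=tree.lengths.copy(), lnL=0.0, n_free_params=4,
            converged=True, n_starts=1, freq=freq,
        )
        beb = beb_sites(aln, tree, fit, FitConfig(beb_grid_points=4))
        assert beb.selected_sites.size == 0

    def test_null_model_rejected(self, m2a_sim, m2a_fits, fast_cfg):
        aln, _, tree = m2a_sim
        with pytest.raises(UsageError):
            beb_sites(aln, tree, m2a_fits["M1a"], fast_cfg)


def test_default_fit_path_free_kappa():
    """The default config (free kappa, exact polish) on a small dataset."""
    from codonsel.sitemodels import dist_m0

    spec = SimulationSpec(
        site_classes=dist_m0(0.3), n_sites=60, seed=17, n_taxa=6, total_length=1.2
    )
    aln, _, tree = simulate_alignment(spec)
    cfg = FitConfig(seed=0, branch_mode="input", polish_maxfev=120)
    m0 = fit_model(aln, tree, "M0", "F3X4", cfg)
    m7 = fit_model(aln, tree, "M7", "F3X4", cfg, m0_fit=m0)
    assert m7.kappa_hat > 0
    assert np.isfinite(m7.lnL)
    assert m7.n_starts >= 3
    assert len(m7.start_lnLs) >= 2
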