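"""Pruning likelihood engine: oracles, invariances, posteriors."""

import itertools

import numpy as np
import pytest

from codonsel.alignment import CodonAlignment
from codonsel.genetics import MISSING, STANDARD_CODE
from codonsel.likelihood import (
    LikelihoodResult,
    SiteClassDistribution,
    empirical_bayes_class_posterior,
    mixture_scale,
    site_likelihoods,
)
from codonsel.ratematrix import FreqModel, GY94Basis, estimate_frequencies
from codonsel.simulate import SimulationSpec, simulate_alignment
from codonsel.trees import PhyloTree


def enumeration_loglik(aln, tree, kappa, freq, dist):
    """Independent oracle: sum over all internal-node state assignments."""
    basis = GY94Basis(kappa, freq)
    c = mixture_scale(basis, dist)
    internals = [v for v in tree.postorder if not tree.is_leaf(v)]
    pi = freq.pi
    row = {t: i for i, t in enumerate(aln.taxa)}
    out = np.empty(aln.n_sites)
    for s in range(aln.n_sites):
        total = 0.0
        for k in range(dist.K):
            om = float(dist.omegas[k])
            f = basis.mu(om) / c
            gen = basis.generator(om)
            Ps = {v: gen.P(tree.lengths[v] * f) for v in tree.branch_nodes}
            sub = 0.0
            for assign in itertools.product(range(61), repeat=len(internals)):
                st = dict(zip(internals, assign))
                for lf in range(tree.n_leaves):
                    st[lf] = aln.codons[row[tree.taxa[lf]], s]
                p = pi[st[tree.root]]
                for v in tree.branch_nodes:
                    parent_state = st[tree.parent[v]]
                    child_state = st[v]
                    if child_state == MISSING:
                        continue  # leaves with missing data marginalize to 1
                    p *= Ps[v][parent_state, child_state]
                sub += p
            total += dist.weights[k] * sub
        out[s] = np.log(total)
    return out


def small_sim(seed, n_taxa, n_sites, dist=None):
    dist = dist or SiteClassDistribution(np.array([1.0]), np.array([0.5]))
    spec = SimulationSpec(
        site_classes=dist, n_sites=n_sites, seed=seed, n_taxa=n_taxa, total_length=1.0
    )
    return simulate_alignment(spec)


def test_single_taxon_site_is_log_pi():
    tree = PhyloTree.from_newick_string("A;")
    i = STANDARD_CODE.index("ATG")
    aln = CodonAlignment(
        taxa=["A"], codons=np.array([[i]], dtype=np.int16), reference_taxon="A"
    )
    freq = FreqModel("FEQUAL", np.full(61, 1 / 61))
    dist = SiteClassDistribution(np.array([1.0]), np.array([0.3]))
    res = site_likelihoods(aln, tree, 2.0, freq, dist)
    assert res.lnL == pytest.approx(np.log(1 / 61))


def test_star_tree_matches_enumeration():
    aln, _, tree = small_sim(5, 3, 2)
    freq = estimate_frequencies(aln, "F61")
    dist = SiteClassDistribution(np.array([0.6, 0.4]), np.array([0.2, 2.5]))
    res = site_likelihoods(aln, tree, 3.0, freq, dist)
    oracle = enumeration_loglik(aln, tree, 3.0, freq, dist)
    np.testing.assert_allclose(res.per_site_lnL, oracle, atol=1e-10)


@pytest.mark.parametrize("seed,n_taxa,n_sites", [(1, 2, 4), (2, 3, 3), (3, 4, 3)])
def test_pruning_equals_enumeration(seed, n_taxa, n_sites):
    """Exhaustive-enumeration oracle on all trees with <= 4 leaves."""
    dist = SiteClassDistribution(np.array([0.5, 0.3, 0.2]), np.array([0.05, 1.0, 4.0]))
    aln, _, tree = small_sim(seed, n_taxa, n_sites, dist)
    # knock in a missing cell to exercise marginalization
    aln.codons[0, 0] = MISSING
    freq = estimate_frequencies(aln, "F3X4")
    res = site_likelihoods(aln, tree, 2.0, freq, dist)
    oracle = enumeration_loglik(aln, tree, 2.0, freq, dist)
    np.testing.assert_allclose(res.per_site_lnL, oracle, atol=1e-9)


def test_mixture_collapse_to_single_class():
    aln, _, tree = small_sim(8, 6, 40)
    freq = estimate_frequencies(aln, "F3X4")
    two = SiteClassDistribution(np.array([0.3, 0.7]), np.array([0.4, 0.4]))
    one = SiteClassDistribution(np.array([1.0]), np.array([0.4]))
    lnL2 = site_likelihoods(aln, tree, 2.0, freq, two).lnL
    lnL1 = site_likelihoods(aln, tree, 2.0, freq, one).lnL
    assert lnL2 == pytest.approx(lnL1, abs=1e-9)


def test_reroot_invariance():
    """The unrooted likelihood does not depend on the rooting used."""
    t1 = PhyloTree.from_newick_string("((A:0.2,B:0.3):0.1,C:0.4,D:0.5);")
    t2 = PhyloTree.from_newick_string("((C:0.4,D:0.5):0.1,A:0.2,B:0.3);")
    dist = SiteClassDistribution(np.array([0.7, 0.3]), np.array([0.1, 2.0]))
    spec = SimulationSpec(site_classes=dist, n_sites=30, seed=4, tree=t1)
    aln, _, _ = simulate_alignment(spec)
    freq = estimate_frequencies(aln, "F3X4")
    lnL1 = site_likelihoods(aln, t1, 2.0, freq, dist).lnL
    lnL2 = site_likelihoods(aln, t2, 2.0, freq, dist).lnL
    assert lnL1 == pytest.approx(lnL2, abs=1e-8)


def test_missing_only_column_does_not_change_lnL():
    aln, _, tree = small_sim(11, 5, 20)
    freq = estimate_frequencies(aln, "F3X4")
    dist = SiteClassDistribution(np.array([1.0]), np.array([0.5]))
    base = site_likelihoods(aln, tree, 2.0, freq, dist).lnL
    padded = CodonAlignment(
        taxa=list(aln.taxa),
        codons=np.hstack([aln.codons, np.full((aln.n_taxa, 1), MISSING, dtype=np.int16)]),
        reference_taxon=aln.reference_taxon,
    )
    res = site_likelihoods(padded, tree, 2.0, freq, dist)
    assert res.lnL == pytest.approx(base, abs=1e-9)
    assert res.per_site_lnL[-1] == pytest.approx(0.0, abs=1e-12)


def test_result_invariants(m2a_sim):
    aln, _, tree = m2a_sim
    freq = estimate_frequencies(aln, "F3X4")
    dist = SiteClassDistribution(np.array([0.5, 0.4, 0.1]), np.array([0.1, 1.0, 5.0]))
    res = site_likelihoods(aln, tree, 2.0, freq, dist)
    assert res.per_site_lnL.sum() == pytest.approx(res.lnL, abs=1e-6)
    np.testing.assert_allclose(res.per_site_class_posterior.sum(axis=1), 1.0, atol=1e-9)


class TestClassPosterior:
    def make_result(self, logliks, weights):
        logliks = np.asarray(logliks, float)
        return LikelihoodResult(
            lnL=0.0,
            per_site_lnL=np.zeros(logliks.shape[0]),
            per_site_class_loglik=logliks,
            per_site_class_posterior=np.zeros_like(logliks),
            dist=SiteClassDistribution(np.asarray(weights), np.ones(len(weights))),
        )

    def test_single_class_posterior_is_one(self):
        res = self.make_result([[0.0], [-3.0]], [1.0])
        np.testing.assert_allclose(empirical_bayes_class_posterior(res), 1.0)

    def test_equal_likelihoods_recover_prior(self):
        res = self.make_result([[-2.0, -2.0]], [0.3, 0.7])
        np.testing.assert_allclose(
            empirical_bayes_class_posterior(res)[0], [0.3, 0.7], atol=1e-12
        )

    def test_hand_computed_two_class(self):
        # likelihoods 0.3 and 0.1 with equal weights -> posterior (0.75, 0.25)
        res = self.make_result([np.log([0.3, 0.1])], [0.5, 0.5])
        np.testing.assert_allclose(
            empirical_bayes_class_posterior(res)[0], [0.75, 0.25], atol=1e-12
        )
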