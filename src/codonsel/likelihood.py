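"""Felsenstein pruning over the 61-codon state space, with site-class mixtures.

Per-site likelihoods are computed with post-order partial vectors, per-node
rescaling (log-scale accumulators) to avoid underflow, and site-pattern
compression: identical alignment columns are computed once and weighted, which
is bit-transparent because every result is re-expanded to original columns.
Missing states contribute a flat partial of 1 over all 61 codons.

Mixture (site-class) models follow the convention that a single normalization
constant c = sum_k p_k * mu(omega_k) scales all classes, so a branch length is
the expected number of substitutions per codon averaged over classes; class k
then evolves along branch t with the unit-rate generator of omega_k at
effective length t * mu(omega_k) / c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .alignment import CodonAlignment
from .errors import NumericalError, ValidationFailure
from .genetics import MISSING
from .ratematrix import FreqModel, GY94Basis
from .trees import PhyloTree

_LOG_FLOOR = -745.0  # log of the smallest positive normal double


@dataclass(frozen=True)
class SiteClassDistribution:
    """A finite mixture of omega classes: weights p_k over rate ratios omega_k."""

    weights: np.ndarray
    omegas: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        om = np.asarray(self.omegas, dtype=float)
        if w.shape != om.shape or w.ndim != 1:
            raise ValidationFailure("weights and omegas must be 1-D and equal length")
        if np.any(w < 0) or np.any(om < 0):
            raise ValidationFailure("weights and omegas must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValidationFailure("class weights must sum to 1")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "omegas", om)

    @property
    def K(self) -> int:
        return int(self.weights.size)


@dataclass
class LikelihoodResult:
    """Log-likelihood with per-site decomposition and class posteriors."""

    lnL: float
    per_site_lnL: np.ndarray
    per_site_class_loglik: np.ndarray  # (n_sites, K), log p(site | class k)
    per_site_class_posterior: np.ndarray  # (n_sites, K)
    dist: SiteClassDistribution


class PruningEngine:
    """Reusable pruning machinery for one (alignment, tree) pair.

    Holds the compressed site patterns and tip partial vectors; the
    rate model (P matrices per branch) is supplied per call, so one engine
    serves every model fitted to the same data.
    """

    def __init__(self, aln: CodonAlignment, tree: PhyloTree, freq: FreqModel):
        tree.validate_against(aln.taxa)
        self.aln = aln
        self.tree = tree
        self.freq = freq
        cols = np.ascontiguousarray(aln.codons.T)
        patterns, inverse, counts = np.unique(
            cols, axis=0, return_inverse=True, return_counts=True
        )
        self.patterns = patterns  # (n_pat, n_taxa) in alignment row order
        self.pattern_of_site = inverse.ravel()
        self.pattern_weights = counts.astype(float)
        self.n_pat = patterns.shape[0]
        # leaf node v of the tree corresponds to alignment row row_of_leaf[v]
        row_index = {name: i for i, name in enumerate(aln.taxa)}
        self.row_of_leaf = np.array([row_index[t] for t in tree.taxa])
        self._tip_partials = self._build_tip_partials()

    def _build_tip_partials(self) -> np.ndarray:
        n_leaves = self.tree.n_leaves
        tp = np.zeros((n_leaves, self.n_pat, 61))
        for v in range(n_leaves):
            states = self.patterns[:, self.row_of_leaf[v]]
            miss = states == MISSING
            tp[v][miss, :] = 1.0
            obs = ~miss
            tp[v][np.nonzero(obs)[0], states[obs]] = 1.0
        return tp

    # ----------------------------------------------------------- single class
    def below_partials(self, P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Post-order partials D and per-pattern log scale factors.

        P has shape (n_nodes, 61, 61); P[v] is the transition matrix along the
        branch above node v (unused for the root).
        """
        tree = self.tree
        D = np.empty((tree.n_nodes, self.n_pat, 61))
        scale = np.zeros((tree.n_nodes, self.n_pat))
        for v in tree.postorder:
            if tree.is_leaf(v):
                D[v] = self._tip_partials[v]
                continue
            acc = None
            sc = np.zeros(self.n_pat)
            for c in tree.children[v]:
                M = D[c] @ P[c].T
                acc = M if acc is None else acc * M
                sc += scale[c]
            m = acc.max(axis=1)
            safe = np.where(m > 0, m, 1.0)
            D[v] = acc / safe[:, None]
            scale[v] = sc + np.where(m > 0, np.log(safe), _LOG_FLOOR)
        return D, scale

    def class_site_logliks(self, P: np.ndarray) -> np.ndarray:
        """Per-pattern log-likelihood under a single rate class."""
        tree = self.tree
        if tree.n_leaves == 1:
            states = self.patterns[:, self.row_of_leaf[0]]
            out = np.empty(self.n_pat)
            for p, s in enumerate(states):
                out[p] = 0.0 if s == MISSING else np.log(self.freq.pi[s])
            return out
        D, scale = self.below_partials(P)
        root = tree.root
        L = D[root] @ self.freq.pi
        with np.errstate(divide="ignore"):
            return np.where(L > 0, np.log(np.where(L > 0, L, 1.0)), _LOG_FLOOR) + scale[root]

    def edge_partials(
        self, P: np.ndarray, D: np.ndarray, scale: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Pre-order "edge-top" partials E.

        E[v][p, j] is the partial likelihood of all data outside the subtree
        of v, for state j at the *parent* end of the branch above v, with the
        root prior pi folded in.  The per-site likelihood restricted to branch
        v factorizes as sum_ij E[v][p,j] P_v[j,i] D[v][p,i], which is what
        branch-length optimization and marginal ancestral reconstruction use.
        The full above-partial of v is E[v] @ P[v].
        """
        tree = self.tree
        E = np.empty((tree.n_nodes, self.n_pat, 61))
        escale = np.zeros((tree.n_nodes, self.n_pat))
        root = tree.root
        A_root = np.broadcast_to(self.freq.pi[None, :], (self.n_pat, 61))
        A = {root: A_root}
        ascale = {root: np.zeros(self.n_pat)}
        for v in reversed(tree.postorder):
            if tree.is_leaf(v):
                continue
            kids = tree.children[v]
            Ms = {c: D[c] @ P[c].T for c in kids}
            for c in kids:
                acc = np.array(A[v], copy=True)
                sc = ascale[v].copy()
                for w in kids:
                    if w is not c:
                        acc *= Ms[w]
                        sc += scale[w]
                m = acc.max(axis=1)
                safe = np.where(m > 0, m, 1.0)
                E[c] = acc / safe[:, None]
                escale[c] = sc + np.where(m > 0, np.log(safe), _LOG_FLOOR)
                if not tree.is_leaf(c):
                    A[c] = E[c] @ P[c]
                    ascale[c] = escale[c]
        return E, escale

    def batched_site_logliks(self, P: np.ndarray) -> np.ndarray:
        """Per-pattern log-likelihoods for a batch of rate models at once.

        P has shape (B, n_nodes, 61, 61); returns (B, n_pat).  Used to fill
        likelihood surfaces where many (omega, scale) grid points share the
        same tree traversal.
        """
        tree = self.tree
        B = P.shape[0]
        if tree.n_leaves == 1:
            return np.broadcast_to(self.class_site_logliks(P[0]), (B, self.n_pat)).copy()
        PT = P.transpose(0, 1, 3, 2)
        D: dict[int, np.ndarray] = {}
        scale: dict[int, np.ndarray] = {}
        for v in tree.postorder:
            if tree.is_leaf(v):
                continue
            acc = None
            sc = np.zeros((B, self.n_pat))
            for c in tree.children[v]:
                if tree.is_leaf(c):
                    Dc = np.broadcast_to(self._tip_partials[c], (B, self.n_pat, 61))
                else:
                    Dc = D.pop(c)
                    sc += scale.pop(c)
                M = np.matmul(Dc, PT[:, c])
                acc = M if acc is None else acc * M
            m = acc.max(axis=2)
            safe = np.where(m > 0, m, 1.0)
            D[v] = acc / safe[:, :, None]
            scale[v] = sc + np.where(m > 0, np.log(safe), _LOG_FLOOR)
        root = tree.root
        L = D[root] @ self.freq.pi
        with np.errstate(divide="ignore"):
            logL = np.where(L > 0, np.log(np.where(L > 0, L, 1.0)), _LOG_FLOOR)
        return logL + scale[root]

    # -------------------------------------------------------------- mixtures
    def class_P_matrices(
        self,
        basis: GY94Basis,
        omega: float,
        length_factor: float,
        lengths: np.ndarray | None = None,
    ) -> np.ndarray:
        """Transition matrices for all branches under one class."""
        tree = self.tree
        if lengths is None:
            lengths = tree.lengths
        gen = basis.generator(omega, scaled=True)
        nodes = tree.branch_nodes
        P = np.empty((tree.n_nodes, 61, 61))
        P[nodes] = gen.P_batch(np.asarray([lengths[v] for v in nodes]) * length_factor)
        return P

    def pattern_loglik(self, P: np.ndarray, pat: int) -> float:
        """Exact log-likelihood of a single site pattern (cheap 61-vectors)."""
        tree = self.tree
        if tree.n_leaves == 1:
            s = self.patterns[pat, self.row_of_leaf[0]]
            return 0.0 if s == MISSING else float(np.log(self.freq.pi[s]))
        D: dict[int, np.ndarray] = {}
        logscale = 0.0
        for v in tree.postorder:
            if tree.is_leaf(v):
                D[v] = self._tip_partials[v, pat]
                continue
            acc = None
            for c in tree.children[v]:
                M = P[c] @ D.pop(c)
                acc = M if acc is None else acc * M
            m = acc.max()
            if m <= 0:
                return _LOG_FLOOR
            D[v] = acc / m
            logscale += np.log(m)
        L = float(self.freq.pi @ D[tree.root])
        if L <= 0:
            return _LOG_FLOOR
        return float(np.log(L)) + logscale

    def expand(self, per_pattern: np.ndarray) -> np.ndarray:
        """Re-expand a per-pattern vector (first axis) to per-site order."""
        return per_pattern[self.pattern_of_site]


def mixture_scale(basis: GY94Basis, dist: SiteClassDistribution) -> float:
    """Class-weighted expected raw substitution rate (the shared normalizer c)."""
    return float(np.sum(dist.weights * (basis.muS + dist.omegas * basis.muN)))


def mixture_pattern_logliks(
    engine: PruningEngine, basis: GY94Basis, dist: SiteClassDistribution
) -> np.ndarray:
    """(K, n_pat) per-class per-pattern log-likelihoods under mixture scaling."""
    c = mixture_scale(basis, dist)
    out = np.empty((dist.K, engine.n_pat))
    for k in range(dist.K):
        f = basis.mu(dist.omegas[k]) / c
        P = engine.class_P_matrices(basis, dist.omegas[k], f)
        out[k] = engine.class_site_logliks(P)
    return out


def site_likelihoods(
    aln: CodonAlignment,
    tree: PhyloTree,
    kappa: float,
    freq: FreqModel,
    dist: SiteClassDistribution,
    engine: PruningEngine | None = None,
) -> LikelihoodResult:
    """Mixture log-likelihood with per-site class posteriors.

    Per-site likelihood is sum_k p_k L(site | omega_k); computation is in log
    space throughout.  A site whose likelihood underflows to zero under every
    class raises :class:`NumericalError` naming the site.
    """
    if engine is None:
        engine = PruningEngine(aln, tree, freq)
    basis = GY94Basis(kappa, freq)
    class_ll = mixture_pattern_logliks(engine, basis, dist)  # (K, n_pat)
    with np.errstate(divide="ignore"):
        logw = np.where(dist.weights > 0, np.log(np.maximum(dist.weights, 1e-300)), -np.inf)
    mix = logsumexp(class_ll + logw[:, None], axis=0)  # (n_pat,)
    dead = ~np.isfinite(mix) | (mix <= _LOG_FLOOR)
    if np.any(dead):
        site = int(np.nonzero(engine.expand(dead))[0][0])
        raise NumericalError(f"zero likelihood at alignment site {site + 1}")
    lnL = float(mix @ engine.pattern_weights)
    post = np.exp(class_ll + logw[:, None] - mix[None, :]).T  # (n_pat, K)
    post /= post.sum(axis=1, keepdims=True)
    return LikelihoodResult(
        lnL=lnL,
        per_site_lnL=engine.expand(mix),
        per_site_class_loglik=engine.expand(class_ll.T),
        per_site_class_posterior=engine.expand(post),
        dist=dist,
    )


def empirical_bayes_class_posterior(result: LikelihoodResult) -> np.ndarray:
    """Naive empirical Bayes posterior: p_k L_s(omega_k) / sum_j p_j L_s(omega_j)."""
    logw = np.where(
        result.dist.weights > 0,
        np.log(np.maximum(result.dist.weights, 1e-300)),
        -np.inf,
    )
    z = result.per_site_class_loglik + logw[None, :]
    z = z - logsumexp(z, axis=1, keepdims=True)
    post = np.exp(z)
    return post / post.sum(axis=1, keepdims=True)


def single_class_loglik(
    aln: CodonAlignment,
    tree: PhyloTree,
    kappa: float,
    freq: FreqModel,
    omega: float,
    engine: PruningEngine | None = None,
) -> float:
    """Convenience wrapper: lnL under a one-class model (M0-style)."""
    dist = SiteClassDistribution(weights=np.array([1.0]), omegas=np.array([float(omega)]))
    return site_likelihoods(aln, tree, kappa, freq, dist, engine=engine).lnL
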