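"""Counting-based rates (SLAC) and per-site selection detectors (FEL, FUBAR).

SLAC reconstructs marginal-ML ancestral codons under the fitted single-ratio
model, classifies the implied substitutions on every branch as synonymous or
nonsynonymous (multi-step changes averaged over stop-free minimal paths), and
normalizes by per-codon mutational-opportunity site counts to give per-site
dN - dS and the gene-average dN/dS.

FEL fits, per site, a synonymous rate alpha and nonsynonymous rate beta by
maximum likelihood (kappa, branch lengths and frequencies fixed from the
global fit) and tests alpha = beta with a chi-square(1) LRT.

FUBAR evaluates site likelihoods on an (alpha, beta) grid and samples grid
weights under a symmetric Dirichlet prior with a seeded Gibbs sampler; the
per-site posterior probability of beta > alpha is the detector output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import betainc
from scipy.stats import chi2

from .alignment import CodonAlignment
from .errors import UsageError
from .genetics import MISSING, NONSYN_SITES, SYN_SITES, count_path_changes
from .likelihood import PruningEngine
from .ratematrix import GY94Basis, TransitionGenerator
from .sitemodels import ModelFit
from .surface import SiteLikelihoodSurface
from .trees import PhyloTree

_LOG_FLOOR = -745.0

# direction codes for FEL
POSITIVE, NEGATIVE, NONE = "positive", "negative", "none"


@dataclass
class AncestralStates:
    """Marginal-ML codon states for every node and site (MISSING where no data)."""

    states: np.ndarray  # (n_nodes, n_sites)
    tree: PhyloTree


@dataclass
class GeneRates:
    gene: str
    avg_dn_ds: float
    avg_dn_minus_ds: float
    n_sites: int
    n_taxa: int
    total_obs_syn: float = 0.0
    total_obs_nonsyn: float = 0.0


@dataclass
class SiteScores:
    """Per-alignment-site detector outputs, filled in by the detectors."""

    n_sites: int
    slac_dn_minus_ds: np.ndarray | None = None
    slac_p: np.ndarray | None = None
    fel_alpha: np.ndarray | None = None
    fel_beta: np.ndarray | None = None
    fel_p: np.ndarray | None = None
    fel_direction: list[str] | None = None
    fubar_post_positive: np.ndarray | None = None
    beb_post: np.ndarray | None = None

    def to_dataframe(self, site_map: np.ndarray | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"site": np.arange(1, self.n_sites + 1)})
        if site_map is not None:
            df["site_ref"] = site_map
        for col in (
            "slac_dn_minus_ds", "slac_p", "fel_alpha", "fel_beta", "fel_p",
            "fubar_post_positive", "beb_post",
        ):
            val = getattr(self, col)
            if val is not None:
                df[col] = val
        if self.fel_direction is not None:
            df["fel_direction"] = self.fel_direction
        return df


# ------------------------------------------------------------- ancestors
def reconstruct_ancestors(
    aln: CodonAlignment, tree: PhyloTree, m0_fit: ModelFit
) -> AncestralStates:
    """Marginal posterior argmax reconstruction under the fitted M0 model.

    Ties break toward the lower codon index (the fixed T,C,A,G-lexicographic
    ordering); columns with no observed data stay MISSING at internal nodes.
    """
    tree_hat = tree.with_lengths(m0_fit.branch_lengths)
    engine = PruningEngine(aln, tree_hat, m0_fit.freq)
    basis = GY94Basis(m0_fit.kappa_hat, m0_fit.freq)
    P = engine.class_P_matrices(basis, m0_fit.params["omega"], 1.0)
    D, dsc = engine.below_partials(P)
    E, _ = engine.edge_partials(P, D, dsc)
    all_missing = np.all(engine.patterns == MISSING, axis=1)  # per pattern
    n_sites = aln.n_sites
    states = np.empty((tree.n_nodes, n_sites), dtype=np.int16)
    for v in range(tree.n_leaves):
        states[v] = aln.codons[engine.row_of_leaf[v]]
    for v in tree.postorder:
        if tree.is_leaf(v):
            continue
        if v == tree.root:
            post = D[v] * engine.freq.pi[None, :]
        else:
            post = (E[v] @ P[v]) * D[v]
        best = np.argmax(post, axis=1).astype(np.int16)
        best[all_missing] = MISSING
        states[v] = engine.expand(best)
    return AncestralStates(states=states, tree=tree)


# ------------------------------------------------------------------ SLAC
_PATH_CACHE: dict[tuple[int, int], tuple[float, float]] = {}


def _path_counts(i: int, j: int) -> tuple[float, float]:
    key = (i, j) if i <= j else (j, i)
    out = _PATH_CACHE.get(key)
    if out is None:
        out = count_path_changes(key[0], key[1])
        _PATH_CACHE[key] = out
    return out


def slac_site_counts(
    aln: CodonAlignment,
    tree: PhyloTree,
    anc: AncestralStates,
    gene: str = "gene",
) -> tuple[SiteScores, GeneRates]:
    """Observed/expected substitution counting over reconstructed branches.

    Per site, observed synonymous and nonsynonymous changes are summed over
    branches (path-averaged for multi-nucleotide changes, stop-free paths
    only); opportunity site counts are the endpoint-averaged per-codon
    mutational opportunities summed over the same branches.  The one-tailed
    positive-selection p-value uses the regularized incomplete beta form of
    the binomial upper tail, which extends smoothly to the fractional counts
    that path averaging produces.
    """
    n_sites = aln.n_sites
    obs_s = np.zeros(n_sites)
    obs_n = np.zeros(n_sites)
    opp_s = np.zeros(n_sites)
    opp_n = np.zeros(n_sites)
    st = anc.states
    for v in tree.branch_nodes:
        u = tree.parent[v]
        pa, ch = st[u], st[v]
        ok = (pa != MISSING) & (ch != MISSING)
        for s in np.nonzero(ok)[0]:
            i, j = int(pa[s]), int(ch[s])
            if i != j:
                syn, nonsyn = _path_counts(i, j)
                obs_s[s] += syn
                obs_n[s] += nonsyn
            opp_s[s] += 0.5 * (SYN_SITES[i] + SYN_SITES[j])
            opp_n[s] += 0.5 * (NONSYN_SITES[i] + NONSYN_SITES[j])
    with np.errstate(divide="ignore", invalid="ignore"):
        dn = np.where(opp_n > 0, obs_n / np.maximum(opp_n, 1e-300), 0.0)
        ds = np.where(opp_s > 0, obs_s / np.maximum(opp_s, 1e-300), 0.0)
    dnmds = dn - ds
    # one-tailed binomial-style p for positive selection at each site
    slac_p = np.ones(n_sites)
    tot = obs_s + obs_n
    with np.errstate(divide="ignore", invalid="ignore"):
        p_n = np.where(opp_s + opp_n > 0, opp_n / np.maximum(opp_s + opp_n, 1e-300), 0.5)
    for s in range(n_sites):
        if tot[s] > 0 and obs_n[s] > 0:
            # P(X >= k) for X ~ Bin(n, p): regularized incomplete beta I_p(k, n-k+1)
            slac_p[s] = float(betainc(obs_n[s], tot[s] - obs_n[s] + 1.0, p_n[s]))
    scores = SiteScores(n_sites=n_sites, slac_dn_minus_ds=dnmds, slac_p=slac_p)
    sum_os, sum_on = obs_s.sum(), obs_n.sum()
    sum_ps, sum_pn = opp_s.sum(), opp_n.sum()
    if sum_os > 0 and sum_ps > 0 and sum_pn > 0:
        avg = (sum_on / sum_pn) / (sum_os / sum_ps)
    else:
        avg = np.inf if sum_on > 0 else 0.0
    rates = GeneRates(
        gene=gene,
        avg_dn_ds=float(avg),
        avg_dn_minus_ds=float(np.mean(dnmds)),
        n_sites=n_sites,
        n_taxa=aln.n_taxa,
        total_obs_syn=float(sum_os),
        total_obs_nonsyn=float(sum_on),
    )
    return scores, rates


# ------------------------------------------------------------------- FEL
def _fel_surface(
    engine: PruningEngine,
    basis: GY94Basis,
    mu_ref: float,
    alpha_range: tuple[float, float] = (0.02, 50.0),
) -> SiteLikelihoodSurface:
    """Surface whose c axis spans the FEL alpha range (c = mu_ref / alpha)."""
    c_grid = np.geomspace(mu_ref / alpha_range[1], mu_ref / alpha_range[0], 14)
    return SiteLikelihoodSurface(engine, basis, c_grid=c_grid)


def _is_invariant_pattern(pattern: np.ndarray) -> bool:
    obs = pattern[pattern != MISSING]
    return obs.size == 0 or np.unique(obs).size == 1


def _exact_ab_pattern_loglik(
    engine: PruningEngine,
    basis: GY94Basis,
    mu_ref: float,
    a: float,
    b: float,
    pat: int,
) -> float:
    """Exact single-pattern lnL under the (alpha, beta) site rate matrix."""
    Q = (a * basis.Rs + b * basis.Rn) / mu_ref
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    gen = TransitionGenerator(Q, basis.freq.pi)
    tree = engine.tree
    nodes = tree.branch_nodes
    P = np.empty((tree.n_nodes, 61, 61))
    P[nodes] = gen.P_batch(np.array([tree.lengths[v] for v in nodes]))
    return engine.pattern_loglik(P, pat)


def fel_site_tests(
    aln: CodonAlignment,
    tree: PhyloTree,
    global_fit: ModelFit,
    scores: SiteScores | None = None,
) -> SiteScores:
    """Per-site FEL across the whole alignment (vectorized over site patterns)."""
    tree_hat = tree.with_lengths(global_fit.branch_lengths)
    engine = PruningEngine(aln, tree_hat, global_fit.freq)
    basis = GY94Basis(global_fit.kappa_hat, global_fit.freq)
    mu_ref = basis.mu(global_fit.params["omega"])
    surface = _fel_surface(engine, basis, mu_ref)
    n_pat = engine.n_pat
    alpha = np.ones(n_pat)
    beta = np.ones(n_pat)
    pvals = np.ones(n_pat)
    direction = np.full(n_pat, NONE, dtype=object)
    lo_a, hi_a = np.log(0.02), np.log(50.0)
    for pat in range(n_pat):
        if _is_invariant_pattern(engine.patterns[pat]):
            continue

        def nll(x: np.ndarray) -> float:
            a = float(np.exp(np.clip(x[0], lo_a, hi_a)))
            b = float(np.exp(np.clip(x[1], np.log(1e-4), np.log(50.0 * 50.0))))
            om = min(b / a, 50.0)
            return -surface.single_pattern_loglik(om, mu_ref / a, pat)

        def nll_null(logr: float) -> float:
            return nll(np.array([logr, logr]))

        res_null = optimize.minimize_scalar(
            nll_null, bounds=(lo_a, hi_a), method="bounded", options={"xatol": 1e-4}
        )
        best_alt = None
        for x0 in (np.array([res_null.x, res_null.x + 0.5]),
                   np.array([res_null.x, res_null.x - 0.5])):
            r = optimize.minimize(
                nll, x0, method="Nelder-Mead",
                options={"maxfev": 120, "xatol": 1e-4, "fatol": 1e-7},
            )
            if best_alt is None or r.fun < best_alt.fun:
                best_alt = r
        a_hat = float(np.exp(np.clip(best_alt.x[0], lo_a, hi_a)))
        b_hat = float(np.exp(np.clip(best_alt.x[1], np.log(1e-4), np.log(2500.0))))
        r_hat = float(np.exp(res_null.x))
        # final statistics are exact at the optimizer's solutions
        ll_null = _exact_ab_pattern_loglik(engine, basis, mu_ref, r_hat, r_hat, pat)
        ll_alt = _exact_ab_pattern_loglik(engine, basis, mu_ref, a_hat, b_hat, pat)
        stat = max(0.0, 2.0 * (ll_alt - ll_null))
        alpha[pat] = a_hat
        beta[pat] = b_hat
        pvals[pat] = float(chi2.sf(stat, 1)) if stat > 0 else 1.0
        if stat > 0:
            direction[pat] = POSITIVE if b_hat > a_hat else NEGATIVE
    scores = scores or SiteScores(n_sites=aln.n_sites)
    scores.fel_alpha = engine.expand(alpha)
    scores.fel_beta = engine.expand(beta)
    scores.fel_p = engine.expand(pvals)
    scores.fel_direction = list(engine.expand(direction))
    return scores


def fel_site_test(
    aln: CodonAlignment, tree: PhyloTree, site: int, global_fit: ModelFit
) -> tuple[float, float, float, str]:
    """FEL for a single 0-based site: (alpha, beta, p, direction)."""
    scores = fel_site_tests(aln.subset_sites(np.array([site])), tree, global_fit)
    return (
        float(scores.fel_alpha[0]),
        float(scores.fel_beta[0]),
        float(scores.fel_p[0]),
        scores.fel_direction[0],
    )


# ----------------------------------------------------------------- FUBAR
def fubar_grid(grid_size: int = 20, max_rate: float = 10.0) -> np.ndarray:
    """Quadratically spaced nonnegative rate grid (denser near zero)."""
    return (np.arange(grid_size) / (grid_size - 1.0)) ** 2 * max_rate


def fubar_site_posteriors(
    aln: CodonAlignment,
    tree: PhyloTree,
    global_fit: ModelFit,
    grid_size: int = 20,
    prior_conc: float = 0.5,
    n_samples: int = 10_000,
    seed: int = 0,
    method: str = "gibbs",
    scores: SiteScores | None = None,
    cells: list[tuple[float, float]] | None = None,
) -> SiteScores:
    """Grid-Bayesian per-site posterior probability of beta > alpha.

    Site likelihoods are precomputed on a grid_size x grid_size (alpha, beta)
    grid; grid weights follow a symmetric Dirichlet(prior_conc) prior and are
    integrated either by a seeded collapsed Gibbs sampler (default) or by an
    EM point estimate (``method='em'``).
    """
    if method == "gibbs" and n_samples < 100:
        raise UsageError("n_samples must be >= 100 for the Gibbs sampler")
    tree_hat = tree.with_lengths(global_fit.branch_lengths)
    engine = PruningEngine(aln, tree_hat, global_fit.freq)
    basis = GY94Basis(global_fit.kappa_hat, global_fit.freq)
    mu_ref = basis.mu(global_fit.params["omega"])
    if cells is None:
        rates = fubar_grid(grid_size)
        cells = [(a, b) for a in rates for b in rates]
    n_cells = len(cells)
    pos_mask = np.array([b > a for a, b in cells])
    # site log-likelihoods per grid cell, computed in batches
    logL = np.empty((n_cells, engine.n_pat))
    chunk = 32
    tree_nodes = tree_hat.n_nodes
    lengths = tree_hat.lengths
    for lo in range(0, n_cells, chunk):
        block = cells[lo : lo + chunk]
        P = np.empty((len(block), tree_nodes, 61, 61))
        for b, (a_r, b_r) in enumerate(block):
            Q = (a_r * basis.Rs + b_r * basis.Rn) / mu_ref
            np.fill_diagonal(Q, 0.0)
            np.fill_diagonal(Q, -Q.sum(axis=1))
            gen = TransitionGenerator(Q, basis.freq.pi)
            for v in tree_hat.branch_nodes:
                P[b, v] = gen.P(lengths[v])
        logL[lo : lo + len(block)] = engine.batched_site_logliks(P)
    # normalize per pattern for numerical stability
    logL -= logL.max(axis=0, keepdims=True)
    L = np.exp(np.maximum(logL, _LOG_FLOOR))
    w_pat = engine.pattern_weights
    rng = np.random.default_rng(seed)
    if method == "em":
        w = np.full(n_cells, 1.0 / n_cells)
        for _ in range(500):
            post = w[:, None] * L
            post /= post.sum(axis=0, keepdims=True)
            counts = post @ w_pat
            w_new = np.maximum(counts + prior_conc - 1.0, 1e-10)
            w_new /= w_new.sum()
            if np.abs(w_new - w).max() < 1e-10:
                w = w_new
                break
            w = w_new
        post = w[:, None] * L
        post /= post.sum(axis=0, keepdims=True)
        mean_pos = pos_mask @ post
    else:
        w = np.full(n_cells, 1.0 / n_cells)
        burn = max(1, n_samples // 5)
        acc = np.zeros(engine.n_pat)
        kept = 0
        for it in range(n_samples):
            probs = w[:, None] * L
            probs /= probs.sum(axis=0, keepdims=True)
            counts = np.zeros(n_cells)
            for pat in range(engine.n_pat):
                counts += rng.multinomial(int(w_pat[pat]), probs[:, pat])
            w = rng.dirichlet(prior_conc + counts)
            if it >= burn:
                acc += pos_mask @ probs
                kept += 1
        mean_pos = acc / max(kept, 1)
    scores = scores or SiteScores(n_sites=aln.n_sites)
    scores.fubar_post_positive = engine.expand(np.clip(mean_pos, 0.0, 1.0))
    return scores
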