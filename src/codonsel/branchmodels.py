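"""Branch models: one-ratio vs free-ratio dN/dS and the dS saturation screen.

The free-ratio (FR) model assigns an independent omega to every branch of the
unrooted phylogeny while sharing kappa and the equilibrium frequencies; it is
compared with the one-ratio (M0) model by a chi-square LRT with degrees of
freedom equal to the number of extra omega parameters (branches - 1).

Per-branch dN and dS are read off the scaled generator: with branch length t
(expected substitutions per codon at that branch's omega), the expected
synonymous substitutions per codon are t * muS / mu(omega), converted to a
per-synonymous-site rate by the neutral site fractions.  dS > 0.25 / dS > 0.5
flags identify branches approaching synonymous-site saturation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .alignment import CodonAlignment
from .errors import UsageError
from .likelihood import PruningEngine
from .ratematrix import FreqModel, GY94Basis, estimate_frequencies
from .sitemodels import FitConfig, LRTResult, ModelFit, chi2_tail
from .trees import PhyloTree

logger = logging.getLogger(__name__)

OMEGA_CAP = 50.0


@dataclass
class BranchRate:
    branch: str  # child-node label
    omega_hat: float
    dn_hat: float
    ds_hat: float
    length: float
    ds_gt_025: bool
    ds_gt_05: bool
    capped: bool = False
    undefined: bool = False


@dataclass
class BranchRates:
    rates: list[BranchRate]

    def __iter__(self):
        return iter(self.rates)

    def __len__(self):
        return len(self.rates)

    @property
    def ds_values(self) -> np.ndarray:
        return np.array([r.ds_hat for r in self.rates])


def _fr_loglik(
    engine: PruningEngine, basis: GY94Basis, omegas: np.ndarray, lengths: np.ndarray
) -> float:
    tree = engine.tree
    P = np.empty((tree.n_nodes, 61, 61))
    for v in tree.branch_nodes:
        P[v] = basis.generator(float(omegas[v]), scaled=True).P(lengths[v])
    return float(engine.class_site_logliks(P) @ engine.pattern_weights)


def fit_free_ratio(
    aln: CodonAlignment,
    tree: PhyloTree,
    freq_kind: str = "F3X4",
    config: FitConfig | None = None,
    m0_fit: ModelFit | None = None,
) -> tuple[ModelFit, BranchRates]:
    """Free-ratio fit: per-branch omega and branch length, shared kappa.

    Starts at the one-ratio solution, then runs coordinate-wise sweeps: each
    branch's (length, omega) pair is optimized with the rest of the tree held
    fixed (using edge-top partials, so each inner evaluation is cheap),
    alternating with a 1-D kappa update, until the lnL gain per sweep drops
    below 1e-4.
    """
    from .sitemodels import fit_model

    config = config or FitConfig()
    if m0_fit is None:
        m0_fit = fit_model(aln, tree, "M0", freq_kind, config)
    freq = m0_fit.freq
    if tree.n_leaves == 2:
        # a two-taxon tree has a single effective branch: the free-ratio model
        # coincides with the one-ratio model, so return it relabeled
        omega0 = m0_fit.params["omega"]
        basis2 = GY94Basis(m0_fit.kappa_hat, freq)
        rates2 = _branch_rate_table(tree, m0_fit.branch_lengths,
                                    np.full(tree.n_nodes, omega0), basis2)
        fr2 = ModelFit(
            model="FR", freq_kind=freq.kind, kappa_hat=m0_fit.kappa_hat,
            params={"omegas": {tree.node_labels[v]: omega0 for v in tree.branch_nodes}},
            branch_lengths=m0_fit.branch_lengths.copy(), lnL=m0_fit.lnL,
            n_free_params=tree.n_branches, converged=m0_fit.converged,
            n_starts=m0_fit.n_starts, freq=freq,
        )
        return fr2, rates2
    tree_hat = tree.with_lengths(m0_fit.branch_lengths)
    engine = PruningEngine(aln, tree_hat, freq)
    n_nodes = tree.n_nodes
    omegas = np.full(n_nodes, m0_fit.params["omega"])
    lengths = m0_fit.branch_lengths.copy()
    kappa = m0_fit.kappa_hat
    basis = GY94Basis(kappa, freq)
    lnL = _fr_loglik(engine, basis, omegas, lengths)
    lo_t, hi_t = np.log(1e-8), np.log(30.0)
    lo_w, hi_w = np.log(1e-4), np.log(OMEGA_CAP)
    for sweep in range(6):
        lnL_before = lnL
        for v in tree.branch_nodes:
            P = np.empty((n_nodes, 61, 61))
            for b in tree.branch_nodes:
                P[b] = basis.generator(float(omegas[b]), scaled=True).P(lengths[b])
            D, dsc = engine.below_partials(P)
            E, esc = engine.edge_partials(P, D, dsc)
            const = esc[v] + dsc[v]
            ev, dv = E[v], D[v]
            w_pat = engine.pattern_weights

            def nll(x: np.ndarray) -> float:
                t = float(np.exp(np.clip(x[0], lo_t, hi_t)))
                om = float(np.exp(np.clip(x[1], lo_w, hi_w)))
                Pt = basis.generator(om, scaled=True).P(t)
                L = ((ev @ Pt) * dv).sum(axis=1)
                with np.errstate(divide="ignore"):
                    logL = np.where(L > 0, np.log(np.maximum(L, 1e-300)), -745.0)
                return -float((logL + const) @ w_pat)

            x0 = np.log([max(lengths[v], 1e-6), max(omegas[v], 1e-3)])
            res = optimize.minimize(
                nll, x0, method="Nelder-Mead",
                options={"maxfev": 80, "xatol": 1e-4, "fatol": 1e-7},
            )
            lengths[v] = float(np.exp(np.clip(res.x[0], lo_t, hi_t)))
            omegas[v] = float(np.exp(np.clip(res.x[1], lo_w, hi_w)))

        def kappa_nll(logk: float) -> float:
            b = GY94Basis(float(np.exp(logk)), freq)
            return -_fr_loglik(engine, b, omegas, lengths)

        res_k = optimize.minimize_scalar(
            kappa_nll,
            bounds=(np.log(config.kappa_bounds[0]), np.log(config.kappa_bounds[1])),
            method="bounded", options={"xatol": 1e-3},
        )
        kappa = float(np.exp(res_k.x))
        basis = GY94Basis(kappa, freq)
        lnL = -res_k.fun
        logger.info("FR sweep %d lnL %.6f", sweep + 1, lnL)
        if lnL - lnL_before < 1e-4:
            break
    rates = _branch_rate_table(tree, lengths, omegas, basis)
    fr_fit = ModelFit(
        model="FR",
        freq_kind=freq.kind,
        kappa_hat=kappa,
        params={
            "omegas": {tree.node_labels[v]: float(omegas[v]) for v in tree.branch_nodes}
        },
        branch_lengths=lengths,
        lnL=float(lnL),
        n_free_params=tree.n_branches,
        converged=True,
        n_starts=1,
        freq=freq,
    )
    return fr_fit, BranchRates(rates)


def _branch_rate_table(
    tree: PhyloTree, lengths: np.ndarray, omegas: np.ndarray, basis: GY94Basis
) -> BranchRates:
    """Per-branch dN/dS decomposition of the scaled generator."""
    neutral_mu = basis.mu(1.0)
    s_frac = basis.muS / neutral_mu
    n_frac = 1.0 - s_frac
    rates = []
    for v in tree.branch_nodes:
        om, t = float(omegas[v]), float(lengths[v])
        undefined = t <= 1e-7
        capped = om >= OMEGA_CAP * (1 - 1e-9)
        mu_b = basis.mu(om)
        es = t * basis.muS / mu_b
        en = t * om * basis.muN / mu_b
        ds = es / (3.0 * s_frac)
        dn = en / (3.0 * n_frac)
        rates.append(
            BranchRate(
                branch=tree.node_labels[v],
                omega_hat=np.nan if undefined else om,
                dn_hat=dn,
                ds_hat=ds,
                length=t,
                ds_gt_025=ds > 0.25,
                ds_gt_05=ds > 0.5,
                capped=capped,
                undefined=undefined,
            )
        )
    return BranchRates(rates)


def fr_lrt(one_ratio_fit: ModelFit, fr_fit: ModelFit, tree: PhyloTree) -> LRTResult:
    """LRT of free-ratio vs one-ratio; df = number of branches - 1."""
    df = tree.n_branches - 1
    if df <= 0:
        raise UsageError("free-ratio LRT undefined: tree has a single branch")
    if one_ratio_fit.freq_kind != fr_fit.freq_kind:
        raise UsageError("fits use different frequency models")
    stat = max(0.0, 2.0 * (fr_fit.lnL - one_ratio_fit.lnL))
    return LRTResult(
        null_model=one_ratio_fit, alt_model=fr_fit, stat=stat, df=df,
        p_value=chi2_tail(stat, df),
    )


@dataclass
class SaturationSummary:
    n_branches: int
    n_over: dict[float, int]
    frac_over: dict[float, float]


def saturation_screen(
    rates: BranchRates, thresholds: tuple[float, ...] = (0.25, 0.5)
) -> SaturationSummary:
    """Count branches whose synonymous divergence exceeds each threshold."""
    ds = rates.ds_values
    n = len(rates)
    n_over = {thr: int((ds > thr).sum()) for thr in thresholds}
    return SaturationSummary(
        n_branches=n,
        n_over=n_over,
        frac_over={thr: (n_over[thr] / n if n else 0.0) for thr in thresholds},
    )


def branch_rates_table(rates: BranchRates):
    import pandas as pd

    return pd.DataFrame(
        [
            (r.branch, r.omega_hat, r.dn_hat, r.ds_hat, r.length,
             r.ds_gt_025, r.ds_gt_05, r.capped, r.undefined)
            for r in rates
        ],
        columns=["branch", "omega", "dn", "ds", "length",
                 "ds_gt_025", "ds_gt_05", "capped", "undefined"],
    )


def annotated_newick(tree: PhyloTree, fr_fit: ModelFit) -> str:
    """Newick string with per-branch omega annotations in comments."""
    omegas = fr_fit.params["omegas"]
    ann = {}
    for v in tree.branch_nodes:
        label = tree.node_labels[v]
        if label in omegas:
            ann[v] = f"omega={omegas[label]:.4g}"
    tree_hat = tree.with_lengths(fr_fit.branch_lengths)
    return tree_hat.to_newick(annotations=ann)


def free_ratio_loglik(
    aln: CodonAlignment,
    tree: PhyloTree,
    kappa: float,
    freq: FreqModel | None = None,
    omegas_by_label: dict[str, float] | None = None,
) -> float:
    """lnL of an explicit per-branch-omega model (exposed for cross-checks)."""
    if freq is None:
        freq = estimate_frequencies(aln, "F3X4")
    engine = PruningEngine(aln, tree, freq)
    basis = GY94Basis(kappa, freq)
    omegas = np.ones(tree.n_nodes)
    if omegas_by_label:
        for v in tree.branch_nodes:
            omegas[v] = omegas_by_label.get(tree.node_labels[v], 1.0)
    return _fr_loglik(engine, basis, omegas, tree.lengths)
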