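"""Site-class model fitting (M0, M1a, M2a, M7, M8), LRTs, and BEB site detection.

The M-series models place each codon site into an omega class: M0 has a single
ratio; M1a/M2a mix a purifying class (omega0 < 1) with a neutral class
(omega = 1) and, in M2a, a selection class (omega2 >= 1); M7/M8 draw omega
from a discretized beta on (0, 1), with M8 adding a selection class
(omega_s >= 1).  Positive selection is inferred when the selection-capable
model fits significantly better than its nested null (M1a vs M2a, M7 vs M8;
chi-square with 2 degrees of freedom for both), and individual sites are then
ranked by their Bayes empirical Bayes posterior probability of omega > 1.

Fitting strategy: kappa, omega classes, and (for M0) branch lengths are
maximized by bounded multi-start local optimization.  Mixture models fix
branch lengths at their M0 estimates, locate the optimum on a precomputed
(omega, scale) likelihood surface, and then re-evaluate -- and optionally
polish -- the solution with exact pruning, so every reported lnL is exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import expit, logit
from scipy.stats import chi2, qmc

from .alignment import CodonAlignment
from .errors import ContentError, UsageError
from .genetics import MISSING
from .likelihood import (
    LikelihoodResult,
    PruningEngine,
    SiteClassDistribution,
    mixture_scale,
)
from .ratematrix import FreqModel, GY94Basis, estimate_frequencies
from .surface import SiteLikelihoodSurface
from .trees import PhyloTree

logger = logging.getLogger(__name__)

MODEL_FREE_PARAMS = {"M0": 1, "M1a": 2, "M2a": 4, "M7": 2, "M8": 4}
_NESTED_PAIRS = {("M0", "M1a"), ("M0", "M2a"), ("M1a", "M2a"), ("M7", "M8"), ("M0", "M8")}

_BETA_SHAPE_BOUNDS = (0.005, 99.0)


# --------------------------------------------------------------------- models
def discretize_beta(p: float, q: float, K: int = 10) -> np.ndarray:
    """Medians of K equal-probability bins of Beta(p, q)."""
    from scipy.special import betaincinv

    p = float(np.clip(p, *_BETA_SHAPE_BOUNDS))
    q = float(np.clip(q, *_BETA_SHAPE_BOUNDS))
    quantiles = (2.0 * np.arange(K) + 1.0) / (2.0 * K)
    return np.clip(betaincinv(p, q, quantiles), 1e-9, 1.0 - 1e-9)


def dist_m0(omega: float) -> SiteClassDistribution:
    return SiteClassDistribution(np.array([1.0]), np.array([float(omega)]))


def dist_m1a(p0: float, omega0: float) -> SiteClassDistribution:
    return SiteClassDistribution(
        np.array([p0, 1.0 - p0]), np.array([float(omega0), 1.0])
    )


def dist_m2a(p0: float, p1: float, omega0: float, omega2: float) -> SiteClassDistribution:
    return SiteClassDistribution(
        np.array([p0, p1, 1.0 - p0 - p1]), np.array([float(omega0), 1.0, float(omega2)])
    )


def dist_m7(p: float, q: float, K: int = 10) -> SiteClassDistribution:
    return SiteClassDistribution(np.full(K, 1.0 / K), discretize_beta(p, q, K))


def dist_m8(
    p0: float, p: float, q: float, omega_s: float, K: int = 10
) -> SiteClassDistribution:
    weights = np.append(np.full(K, p0 / K), 1.0 - p0)
    omegas = np.append(discretize_beta(p, q, K), float(omega_s))
    return SiteClassDistribution(weights, omegas)


# ---------------------------------------------------------------- fit results
@dataclass
class FitConfig:
    """Optimizer and model-discretization settings."""

    n_starts: int = 3
    seed: int = 0
    beta_K: int = 10
    omega_max: float = 50.0
    kappa_bounds: tuple[float, float] = (0.01, 100.0)
    branch_mode: str = "estimate"  # 'estimate' | 'scale' | 'input' (M0 only)
    m0_rounds: int = 2
    m0_maxfev: int = 300
    kappa_mode: str = "free"  # 'free' | 'm0' (mixture models)
    polish: bool = True
    polish_maxfev: int = 250
    surface_maxfev: int = 400
    surface_omega_grid: np.ndarray | None = None
    surface_c_grid: np.ndarray | None = None
    beb_grid_points: int = 10
    convergence_tol: float = 0.01


@dataclass
class ModelFit:
    """Maximum-likelihood fit of one site-class model."""

    model: str
    freq_kind: str
    kappa_hat: float
    params: dict
    branch_lengths: np.ndarray
    lnL: float
    n_free_params: int
    converged: bool
    n_starts: int
    freq: FreqModel
    start_lnLs: list = field(default_factory=list)

    @property
    def dist(self) -> SiteClassDistribution:
        return make_dist(self.model, self.params)

    def fitted_tree(self, tree: PhyloTree) -> PhyloTree:
        return tree.with_lengths(self.branch_lengths)


@dataclass
class LRTResult:
    null_model: ModelFit
    alt_model: ModelFit
    stat: float
    df: int
    p_value: float


@dataclass
class BEBScores:
    """Per-site posterior probabilities that omega > 1 (BEB)."""

    post_positive: np.ndarray
    post_mean_omega: np.ndarray
    cutoff: float = 0.90

    @property
    def selected_sites(self) -> np.ndarray:
        """0-based alignment columns with P(omega > 1) >= cutoff."""
        return np.nonzero(self.post_positive >= self.cutoff)[0]


def make_dist(model: str, params: dict, K: int = 10) -> SiteClassDistribution:
    if model == "M0":
        return dist_m0(params["omega"])
    if model == "M1a":
        return dist_m1a(params["p0"], params["omega0"])
    if model == "M2a":
        return dist_m2a(params["p0"], params["p1"], params["omega0"], params["omega2"])
    if model == "M7":
        return dist_m7(params["p"], params["q"], params.get("K", K))
    if model == "M8":
        return dist_m8(
            params["p0"], params["p"], params["q"], params["omega_s"], params.get("K", K)
        )
    raise UsageError(f"unknown model {model!r}")


def chi2_tail(stat: float, df: int) -> float:
    """Upper-tail chi-square probability; closed form exp(-stat/2) for df = 2."""
    if df == 2:
        return float(np.exp(-stat / 2.0))
    return float(chi2.sf(stat, df))


# ------------------------------------------------------- parameter transforms
def _pack(model: str, params: dict, omega_max: float) -> np.ndarray:
    def lg(x, lo=1e-7, hi=1 - 1e-7):
        return logit(np.clip(x, lo, hi))

    if model == "M1a":
        return np.array([lg(params["p0"]), lg(params["omega0"])])
    if model == "M2a":
        p0, p1 = params["p0"], params["p1"]
        r = p1 / max(1.0 - p0, 1e-12)
        s = (params["omega2"] - 1.0) / (omega_max - 1.0)
        return np.array([lg(p0), lg(r), lg(params["omega0"]), lg(s)])
    if model == "M7":
        return np.log([params["p"], params["q"]])
    if model == "M8":
        s = (params["omega_s"] - 1.0) / (omega_max - 1.0)
        return np.concatenate(
            [[lg(params["p0"])], np.log([params["p"], params["q"]]), [lg(s)]]
        )
    raise UsageError(f"no transform for model {model!r}")


def _unpack(model: str, x: np.ndarray, omega_max: float, K: int) -> dict:
    if model == "M1a":
        return {"p0": float(expit(x[0])), "omega0": float(expit(x[1]))}
    if model == "M2a":
        p0 = float(expit(x[0]))
        p1 = (1.0 - p0) * float(expit(x[1]))
        return {
            "p0": p0,
            "p1": p1,
            "omega0": float(expit(x[2])),
            "omega2": 1.0 + (omega_max - 1.0) * float(expit(x[3])),
        }
    if model == "M7":
        p, q = np.exp(np.clip(x, np.log(_BETA_SHAPE_BOUNDS[0]), np.log(_BETA_SHAPE_BOUNDS[1])))
        return {"p": float(p), "q": float(q), "K": K}
    if model == "M8":
        p, q = np.exp(
            np.clip(x[1:3], np.log(_BETA_SHAPE_BOUNDS[0]), np.log(_BETA_SHAPE_BOUNDS[1]))
        )
        return {
            "p0": float(expit(x[0])),
            "p": float(p),
            "q": float(q),
            "omega_s": 1.0 + (omega_max - 1.0) * float(expit(x[3])),
            "K": K,
        }
    raise UsageError(f"no transform for model {model!r}")


_DEFAULT_STARTS = {
    "M1a": {"p0": 0.7, "omega0": 0.1},
    "M2a": {"p0": 0.6, "p1": 0.3, "omega0": 0.1, "omega2": 3.0},
    "M7": {"p": 0.5, "q": 2.0},
    "M8": {"p0": 0.9, "p": 0.5, "q": 2.0, "omega_s": 3.0},
}

_LHS_RANGES = {  # transformed-coordinate ranges for Latin-hypercube starts
    "M1a": [(-2.5, 2.5), (-4.0, 1.5)],
    "M2a": [(-2.0, 2.0), (-2.0, 2.0), (-4.0, 1.5), (-3.5, 0.5)],
    "M7": [(np.log(0.08), np.log(5.0)), (np.log(0.2), np.log(8.0))],
    "M8": [(-1.0, 3.5), (np.log(0.08), np.log(5.0)), (np.log(0.2), np.log(8.0)), (-3.5, 0.5)],
}


def _start_points(model: str, config: FitConfig) -> list[np.ndarray]:
    starts = [_pack(model, _DEFAULT_STARTS[model], config.omega_max)]
    extra = config.n_starts - 1
    if extra > 0:
        ranges = np.array(_LHS_RANGES[model])
        sampler = qmc.LatinHypercube(d=ranges.shape[0], seed=config.seed)
        unit = sampler.random(extra)
        starts.extend(ranges[:, 0] + unit * (ranges[:, 1] - ranges[:, 0]))
    return starts


# ------------------------------------------------------------------ M0 fitting
def _has_variation(aln: CodonAlignment) -> bool:
    for col in aln.codons.T:
        obs = col[col != MISSING]
        if obs.size and np.unique(obs).size > 1:
            return True
    return False


def _m0_loglik(
    engine: PruningEngine, freq: FreqModel, kappa: float, omega: float, lengths: np.ndarray
) -> float:
    basis = GY94Basis(kappa, freq)
    P = engine.class_P_matrices(basis, omega, 1.0, lengths)
    return float(engine.class_site_logliks(P) @ engine.pattern_weights)


def _optimize_branches(
    engine: PruningEngine,
    freq: FreqModel,
    kappa: float,
    omega: float,
    lengths: np.ndarray,
) -> np.ndarray:
    """One coordinate-wise sweep of per-branch Brent optimization."""
    tree = engine.tree
    basis = GY94Basis(kappa, freq)
    gen = basis.generator(omega, scaled=True)
    w = engine.pattern_weights
    lengths = lengths.copy()
    for v in tree.branch_nodes:
        P = engine.class_P_matrices(basis, omega, 1.0, lengths)
        D, dsc = engine.below_partials(P)
        E, esc = engine.edge_partials(P, D, dsc)
        const = esc[v] + dsc[v]
        ev, dv = E[v], D[v]

        def nll(logt: float) -> float:
            L = ((ev @ gen.P(np.exp(logt))) * dv).sum(axis=1)
            with np.errstate(divide="ignore"):
                logL = np.where(L > 0, np.log(np.maximum(L, 1e-300)), -745.0)
            return -float((logL + const) @ w)

        res = optimize.minimize_scalar(
            nll, bounds=(np.log(1e-7), np.log(30.0)), method="bounded",
            options={"xatol": 1e-4},
        )
        lengths[v] = float(np.exp(res.x))
    return lengths


def _fit_m0(
    aln: CodonAlignment,
    tree: PhyloTree,
    freq: FreqModel,
    engine: PruningEngine,
    config: FitConfig,
) -> ModelFit:
    if not _has_variation(aln):
        raise ContentError(
            "alignment reduces to a single unique sequence; M0 omega is undefined"
        )
    lengths0 = tree.lengths.copy()
    if not np.any(lengths0[np.array(tree.branch_nodes)] > 0):
        lengths0 = lengths0 + 0.1  # no usable input lengths; start somewhere positive
    lo_k, hi_k = np.log(config.kappa_bounds)

    def objective(x: np.ndarray) -> float:
        kappa = float(np.exp(np.clip(x[0], lo_k, hi_k)))
        omega = float(np.exp(np.clip(x[1], np.log(1e-5), np.log(config.omega_max))))
        scale = float(np.exp(np.clip(x[2], -8.0, 5.0)))
        return -_m0_loglik(engine, freq, kappa, omega, lengths0 * scale)

    starts = [np.array([np.log(2.0), np.log(0.4), 0.0])]
    if config.n_starts > 1:
        sampler = qmc.LatinHypercube(d=3, seed=config.seed)
        unit = sampler.random(config.n_starts - 1)
        lo = np.array([np.log(0.5), np.log(0.02), -1.0])
        hi = np.array([np.log(10.0), np.log(3.0), 1.0])
        starts.extend(lo + unit * (hi - lo))
    best = None
    start_lnLs = []
    for x0 in starts:
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options={"maxfev": config.m0_maxfev, "xatol": 1e-4, "fatol": 1e-6},
        )
        start_lnLs.append(-res.fun)
        logger.info("M0 start %s -> lnL %.6f", np.round(x0, 3), -res.fun)
        if best is None or res.fun < best.fun:
            best = res
    kappa = float(np.exp(np.clip(best.x[0], lo_k, hi_k)))
    omega = float(np.exp(np.clip(best.x[1], np.log(1e-5), np.log(config.omega_max))))
    lengths = lengths0 * float(np.exp(np.clip(best.x[2], -8.0, 5.0)))
    lnL = -best.fun
    if config.branch_mode == "estimate":
        for _ in range(config.m0_rounds):
            lengths = _optimize_branches(engine, freq, kappa, omega, lengths)

            def ko_obj(x: np.ndarray) -> float:
                k = float(np.exp(np.clip(x[0], lo_k, hi_k)))
                om = float(np.exp(np.clip(x[1], np.log(1e-5), np.log(config.omega_max))))
                return -_m0_loglik(engine, freq, k, om, lengths)

            res = optimize.minimize(
                ko_obj, np.log([kappa, omega]), method="Nelder-Mead",
                options={"maxfev": min(200, config.m0_maxfev), "xatol": 1e-5, "fatol": 1e-7},
            )
            kappa = float(np.exp(np.clip(res.x[0], lo_k, hi_k)))
            omega = float(np.exp(np.clip(res.x[1], np.log(1e-5), np.log(config.omega_max))))
            lnL = -res.fun
    elif config.branch_mode == "input":
        lengths = lengths0
        lnL = _m0_loglik(engine, freq, kappa, omega, lengths)
    ranked = sorted(start_lnLs, reverse=True)
    converged = len(ranked) < 2 or (ranked[0] - ranked[1]) <= config.convergence_tol
    return ModelFit(
        model="M0",
        freq_kind=freq.kind,
        kappa_hat=kappa,
        params={"omega": omega},
        branch_lengths=lengths,
        lnL=float(lnL),
        n_free_params=MODEL_FREE_PARAMS["M0"],
        converged=bool(converged),
        n_starts=len(starts),
        freq=freq,
        start_lnLs=start_lnLs,
    )


# -------------------------------------------------------------- mixture fitting
def _exact_mixture_loglik(
    engine: PruningEngine, freq: FreqModel, kappa: float, dist: SiteClassDistribution
) -> float:
    from scipy.special import logsumexp

    from .likelihood import mixture_pattern_logliks

    basis = GY94Basis(kappa, freq)
    class_ll = mixture_pattern_logliks(engine, basis, dist)
    with np.errstate(divide="ignore"):
        logw = np.where(dist.weights > 0, np.log(np.maximum(dist.weights, 1e-300)), -np.inf)
    mix = logsumexp(class_ll + logw[:, None], axis=0)
    return float(mix @ engine.pattern_weights)


def make_surface(
    aln: CodonAlignment,
    tree: PhyloTree,
    m0_fit: ModelFit,
    config: FitConfig | None = None,
) -> SiteLikelihoodSurface:
    """Likelihood surface at the M0 solution, shareable across mixture fits."""
    config = config or FitConfig()
    tree_hat = tree.with_lengths(m0_fit.branch_lengths)
    engine = PruningEngine(aln, tree_hat, m0_fit.freq)
    basis = GY94Basis(m0_fit.kappa_hat, m0_fit.freq)
    return SiteLikelihoodSurface(
        engine, basis,
        omega_grid=config.surface_omega_grid,
        c_grid=config.surface_c_grid,
    )


def _fit_mixture(
    aln: CodonAlignment,
    tree: PhyloTree,
    model: str,
    freq: FreqModel,
    config: FitConfig,
    m0_fit: ModelFit,
    null_fit: ModelFit | None,
    surface: SiteLikelihoodSurface | None = None,
) -> ModelFit:
    lengths = m0_fit.branch_lengths
    kappa0 = m0_fit.kappa_hat
    if surface is None:
        surface = make_surface(aln, tree, m0_fit, config)
    engine = surface.engine
    K = config.beta_K

    def surf_nll(x: np.ndarray) -> float:
        return -surface.mixture_loglik(make_dist(model, _unpack(model, x, config.omega_max, K)))

    dim = len(_pack(model, _DEFAULT_STARTS[model], config.omega_max))
    maxfev = min(config.surface_maxfev, 80 * dim)
    candidates: list[tuple[float, np.ndarray]] = []
    for x0 in _start_points(model, config):
        res = optimize.minimize(
            surf_nll, x0, method="Nelder-Mead",
            options={"maxfev": maxfev, "xatol": 1e-4, "fatol": 1e-7},
        )
        candidates.append((-res.fun, res.x))
        logger.info("%s surface start -> lnL %.6f", model, -res.fun)
    candidates.sort(key=lambda c: -c[0])

    def exact_lnL(x: np.ndarray, kappa: float) -> float:
        return _exact_mixture_loglik(
            engine, freq, kappa, make_dist(model, _unpack(model, x, config.omega_max, K))
        )

    free_kappa = config.kappa_mode == "free"
    lo_k, hi_k = np.log(config.kappa_bounds)

    def polish(x0: np.ndarray, kappa: float, maxfev: int) -> tuple[float, np.ndarray, float]:
        if config.polish and maxfev > 0:
            if free_kappa:
                z0 = np.concatenate([[np.log(kappa)], x0])

                def nll(z: np.ndarray) -> float:
                    k = float(np.exp(np.clip(z[0], lo_k, hi_k)))
                    return -exact_lnL(z[1:], k)

                res = optimize.minimize(
                    nll, z0, method="Nelder-Mead",
                    options={"maxfev": maxfev, "xatol": 1e-4, "fatol": 1e-6},
                )
                k_hat = float(np.exp(np.clip(res.x[0], lo_k, hi_k)))
                return -res.fun, res.x[1:], k_hat
            res = optimize.minimize(
                lambda z: -exact_lnL(z, kappa), x0, method="Nelder-Mead",
                options={"maxfev": maxfev, "xatol": 1e-4, "fatol": 1e-6},
            )
            return -res.fun, res.x, kappa
        return exact_lnL(x0, kappa), x0, kappa

    n_polish = min(2, len(candidates))
    results = []
    for lnl_surf, x in candidates[:n_polish]:
        results.append(polish(x, kappa0, config.polish_maxfev))
    for lnl_surf, x in candidates[n_polish:]:
        results.append((exact_lnL(x, kappa0), x, kappa0))
    # exact embedding of the fitted null guarantees nesting of the LRT
    if null_fit is not None:
        emb = _embed_null(model, null_fit, config)
        if emb is not None:
            x_emb = _pack(model, emb, config.omega_max)
            k_emb = null_fit.kappa_hat
            results.append((exact_lnL(x_emb, k_emb), x_emb, k_emb))
    results.sort(key=lambda r: -r[0])
    lnL, x_best, kappa_hat = results[0]
    start_lnLs = [r[0] for r in results]
    converged = len(start_lnLs) < 2 or (start_lnLs[0] - start_lnLs[1]) <= config.convergence_tol
    params = _unpack(model, x_best, config.omega_max, K)
    return ModelFit(
        model=model,
        freq_kind=freq.kind,
        kappa_hat=float(kappa_hat),
        params=params,
        branch_lengths=lengths.copy(),
        lnL=float(lnL),
        n_free_params=MODEL_FREE_PARAMS[model],
        converged=bool(converged),
        n_starts=len(candidates),
        freq=freq,
        start_lnLs=start_lnLs,
    )


def _embed_null(model: str, null_fit: ModelFit, config: FitConfig) -> dict | None:
    """Parameters of `model` that reproduce the fitted null exactly."""
    if model == "M2a" and null_fit.model == "M1a":
        return {
            "p0": null_fit.params["p0"],
            "p1": 1.0 - null_fit.params["p0"],
            "omega0": null_fit.params["omega0"],
            "omega2": 1.0,
        }
    if model == "M8" and null_fit.model == "M7":
        return {
            "p0": 1.0,
            "p": null_fit.params["p"],
            "q": null_fit.params["q"],
            "omega_s": 2.0,
            "K": config.beta_K,
        }
    return None


# ------------------------------------------------------------------ public API
def fit_model(
    aln: CodonAlignment,
    tree: PhyloTree,
    model: str,
    freq_kind: str = "F3X4",
    config: FitConfig | None = None,
    *,
    freq: FreqModel | None = None,
    m0_fit: ModelFit | None = None,
    null_fit: ModelFit | None = None,
    surface: SiteLikelihoodSurface | None = None,
) -> ModelFit:
    """Fit a site-class model by multi-start bounded maximum likelihood.

    M0 optimizes kappa, omega and branch lengths; the mixture models fix the
    branch lengths at the M0 estimates (pass ``m0_fit`` to avoid refitting).
    ``null_fit`` may carry the fitted null of an LRT pair, whose exact
    embedding is added to the candidate set so lnL(alt) >= lnL(null) holds.
    """
    if model not in MODEL_FREE_PARAMS:
        raise UsageError(f"unknown model {model!r}")
    config = config or FitConfig()
    if freq is None:
        freq = estimate_frequencies(aln, freq_kind)
    tree.validate_against(aln.taxa)
    if model == "M0":
        engine = PruningEngine(aln, tree, freq)
        return _fit_m0(aln, tree, freq, engine, config)
    if m0_fit is None:
        m0_fit = fit_model(aln, tree, "M0", freq_kind, config, freq=freq)
    return _fit_mixture(aln, tree, model, freq, config, m0_fit, null_fit, surface=surface)


def lrt(null_fit: ModelFit, alt_fit: ModelFit) -> LRTResult:
    """Likelihood ratio test of nested site-class models.

    The statistic 2(lnL_alt - lnL_null) is clipped at zero (boundary
    artifacts); for the df = 2 comparisons the tail probability is the closed
    form exp(-stat/2).
    """
    if null_fit.freq_kind != alt_fit.freq_kind:
        raise UsageError(
            f"LRT across frequency models ({null_fit.freq_kind} vs {alt_fit.freq_kind})"
        )
    if (null_fit.model, alt_fit.model) not in _NESTED_PAIRS:
        raise UsageError(f"{null_fit.model} is not nested in {alt_fit.model}")
    df = alt_fit.n_free_params - null_fit.n_free_params
    stat = max(0.0, 2.0 * (alt_fit.lnL - null_fit.lnL))
    return LRTResult(
        null_model=null_fit,
        alt_model=alt_fit,
        stat=stat,
        df=df,
        p_value=chi2_tail(stat, df),
    )


# ------------------------------------------------------------------------ BEB
def _beb_grids(model: str, n: int, params_mle: dict | None = None) -> dict[str, np.ndarray]:
    mids = (np.arange(n) + 0.5) / n
    if model == "M2a":
        return {
            "p0": mids, "r": mids, "omega0": mids, "omega2": 1.0 + 10.0 * mids,
        }
    return {  # M8
        "p0": mids, "p": 2.0 * mids, "q": 2.0 * mids, "omega_s": 1.0 + 10.0 * mids,
    }


def beb_sites(
    aln: CodonAlignment,
    tree: PhyloTree,
    alt_fit: ModelFit,
    config: FitConfig | None = None,
    grids: dict[str, np.ndarray] | None = None,
) -> BEBScores:
    """Bayes empirical Bayes site posteriors under a fitted M2a or M8 model.

    Mixture parameters are integrated over a uniform prior grid (default 10
    points per dimension); kappa and branch lengths stay fixed at their MLEs.
    P(omega > 1) at a site is the posterior mass of the selection class.  A
    degenerate single-point grid reduces to the naive empirical Bayes
    posterior at the MLE, which is evaluated exactly.
    """
    if alt_fit.model not in ("M2a", "M8"):
        raise UsageError(f"BEB requires an M2a or M8 fit, got {alt_fit.model}")
    config = config or FitConfig()
    freq = alt_fit.freq
    tree_hat = tree.with_lengths(alt_fit.branch_lengths)
    engine = PruningEngine(aln, tree_hat, freq)
    basis = GY94Basis(alt_fit.kappa_hat, freq)
    if grids is None:
        grids = _beb_grids(alt_fit.model, config.beb_grid_points)
    keys = list(grids)
    axes = [np.atleast_1d(np.asarray(grids[k], float)) for k in keys]
    mesh = np.stack([m.ravel() for m in np.meshgrid(*axes, indexing="ij")], axis=1)
    n_grid = mesh.shape[0]
    K = config.beta_K

    def theta_dist(row: np.ndarray) -> SiteClassDistribution:
        d = dict(zip(keys, row))
        if alt_fit.model == "M2a":
            p0 = d["p0"]
            p1 = (1.0 - p0) * d["r"]
            return dist_m2a(p0, p1, d["omega0"], d["omega2"])
        return dist_m8(d["p0"], d["p"], d["q"], d["omega_s"], K)

    exact = n_grid <= 50
    surface = None
    if not exact:
        surface = SiteLikelihoodSurface(
            engine, basis,
            omega_grid=config.surface_omega_grid,
            c_grid=config.surface_c_grid,
        )
    from scipy.special import logsumexp

    w_pat = engine.pattern_weights
    data_loglik = np.empty(n_grid)
    psel = np.empty((n_grid, engine.n_pat))
    pmean = np.empty((n_grid, engine.n_pat))
    for g in range(n_grid):
        dist = theta_dist(mesh[g])
        if exact:
            from .likelihood import mixture_pattern_logliks

            class_ll = mixture_pattern_logliks(engine, basis, dist)
        else:
            c = mixture_scale(basis, dist)
            class_ll = surface.class_logliks_at_c(dist.omegas, c)
        with np.errstate(divide="ignore"):
            logw = np.where(
                dist.weights > 0, np.log(np.maximum(dist.weights, 1e-300)), -np.inf
            )
        z = class_ll + logw[:, None]
        mix = logsumexp(z, axis=0)
        post = np.exp(z - mix[None, :])
        sel = dist.omegas > 1.0
        psel[g] = post[sel].sum(axis=0)
        pmean[g] = dist.omegas @ post
        data_loglik[g] = float(mix @ w_pat)
    log_post = data_loglik - logsumexp(data_loglik)
    wts = np.exp(log_post)
    post_positive = engine.expand(wts @ psel)
    post_mean_omega = engine.expand(wts @ pmean)
    return BEBScores(
        post_positive=np.clip(post_positive, 0.0, 1.0),
        post_mean_omega=post_mean_omega,
        cutoff=0.90,
    )


def naive_eb_positive(result: LikelihoodResult) -> np.ndarray:
    """NEB P(omega > 1) per site from a mixture LikelihoodResult."""
    sel = result.dist.omegas > 1.0
    return result.per_site_class_posterior[:, sel].sum(axis=1)
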