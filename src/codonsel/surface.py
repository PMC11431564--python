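"""Precomputed per-site likelihood surfaces over (omega, scale).

Site-class fits, BEB integration, and per-site rate tests all evaluate the
same quantity many thousands of times: the per-site likelihood of the data
under a single omega class whose branch lengths are rescaled by a smooth
factor.  This module precomputes those per-site log-likelihoods on an
(omega, c) grid -- c being the mixture normalization constant, so the class
with rate ratio omega evolves at branch-length multiplier mu(omega)/c -- and
interpolates between grid nodes (cubic along omega, linear along log c).

The surface only *guides* optimization; every reported lnL is re-evaluated
exactly at the chosen parameter values by the pruning engine.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

from .likelihood import PruningEngine, SiteClassDistribution, mixture_scale
from .ratematrix import GY94Basis

#: default omega grid: logarithmic over [1e-4, 50]; per-site log-likelihood is
#: close to linear in log(omega) at small omega, where beta classes pile up
DEFAULT_OMEGA_GRID = np.geomspace(1e-4, 50.0, 32)


def default_c_grid(basis: GY94Basis, lo_omega: float = 0.0, hi_omega: float = 3.0,
                   n: int = 10) -> np.ndarray:
    """Geometric grid of mixture normalizers spanning plausible mixture means."""
    lo = basis.mu(lo_omega) * 0.8
    hi = basis.mu(hi_omega) * 1.25
    return np.geomspace(lo, hi, n)


class SiteLikelihoodSurface:
    """Interpolable per-pattern log-likelihoods L_s(omega, c).

    Parameters
    ----------
    engine:
        Pruning engine for the (alignment, tree) pair; tree branch lengths are
        taken as fixed (typically the M0 estimates).
    basis:
        GY94 exchange basis at fixed kappa and frequencies.
    """

    def __init__(
        self,
        engine: PruningEngine,
        basis: GY94Basis,
        omega_grid: np.ndarray | None = None,
        c_grid: np.ndarray | None = None,
        chunk: int = 24,
    ):
        self.engine = engine
        self.basis = basis
        self.omega_grid = (
            np.asarray(omega_grid, float) if omega_grid is not None else DEFAULT_OMEGA_GRID
        )
        self.c_grid = (
            np.asarray(c_grid, float) if c_grid is not None else default_c_grid(basis)
        )
        self.log_c_grid = np.log(self.c_grid)
        # interpolate over log(omega); clamped at the grid ends
        self.u_grid = np.log(self.omega_grid)
        tree = engine.tree
        n_om, n_c = self.omega_grid.size, self.c_grid.size
        values = np.empty((n_om, n_c, engine.n_pat))
        lengths = tree.lengths
        branch_nodes = tree.branch_nodes
        bl = np.array([lengths[v] for v in branch_nodes])
        for i, om in enumerate(self.omega_grid):
            gen = basis.generator(float(om), scaled=True)
            f = basis.mu(float(om)) / self.c_grid  # (n_c,)
            ts = f[:, None] * bl[None, :]  # (n_c, n_branches)
            # batched P = (left * exp(w t)) @ right over all (c, branch) pairs
            E = np.exp(gen._w[None, None, :] * ts[:, :, None])
            P_flat = np.matmul(gen._left[None, None, :, :] * E[:, :, None, :], gen._right)
            np.clip(P_flat, 0.0, None, out=P_flat)
            P = np.zeros((n_c, tree.n_nodes, 61, 61))
            for b, v in enumerate(branch_nodes):
                P[:, v] = P_flat[:, b]
            values[i] = engine.batched_site_logliks(P)
        self.values = values
        # tensor-product natural bicubic spline: applying CubicSpline to the
        # c-axis coefficients along omega is legal because spline construction
        # is linear in the data; yields per-cell coefficients evaluated with
        # plain polynomial arithmetic (no per-query spline solves)
        cs_c = CubicSpline(self.log_c_grid, values, axis=1)
        self._C = CubicSpline(self.u_grid, cs_c.c, axis=2).c
        # shape: (4 [omega poly], n_om-1, 4 [c poly], n_c-1, n_pat)

    # ------------------------------------------------------------------ query
    def pattern_logliks(self, omegas: np.ndarray, cs: np.ndarray) -> np.ndarray:
        """Interpolated per-pattern log-likelihoods, shape (K, n_pat).

        Queries are clamped to the grid's support.
        """
        om = np.clip(np.asarray(omegas, float), self.omega_grid[0], self.omega_grid[-1])
        u = np.log(om)
        logc = np.clip(
            np.log(np.asarray(cs, float)), self.log_c_grid[0], self.log_c_grid[-1]
        )
        K = u.size
        iu = np.clip(np.searchsorted(self.u_grid, u) - 1, 0, self.u_grid.size - 2)
        ic = np.clip(
            np.searchsorted(self.log_c_grid, logc) - 1, 0, self.log_c_grid.size - 2
        )
        B = self._C[:, iu, :, :, :][:, np.arange(K), :, ic, :]  # (K, 4, 4, n_pat)
        powers = np.array([3, 2, 1, 0])
        pu = (u - self.u_grid[iu])[None, :] ** powers[:, None]  # (4, K)
        pc = (logc - self.log_c_grid[ic])[None, :] ** powers[:, None]
        return np.einsum("kmnp,mk,nk->kp", B, pu, pc)

    def single_pattern_loglik(self, omega: float, c: float, pat: int) -> float:
        """Interpolated log-likelihood of one site pattern at one (omega, c)."""
        om = float(np.clip(omega, self.omega_grid[0], self.omega_grid[-1]))
        u = np.log(om)
        logc = float(np.clip(np.log(c), self.log_c_grid[0], self.log_c_grid[-1]))
        iu = int(np.clip(np.searchsorted(self.u_grid, u) - 1, 0, self.u_grid.size - 2))
        ic = int(
            np.clip(np.searchsorted(self.log_c_grid, logc) - 1, 0, self.log_c_grid.size - 2)
        )
        B = self._C[:, iu, :, ic, pat]  # (4, 4)
        du = u - self.u_grid[iu]
        dc = logc - self.log_c_grid[ic]
        pu = du ** np.array([3.0, 2.0, 1.0, 0.0])
        pc = dc ** np.array([3.0, 2.0, 1.0, 0.0])
        return float(pu @ B @ pc)

    def mixture_pattern_logliks(self, dist: SiteClassDistribution) -> np.ndarray:
        """Per-pattern mixture log-likelihood under shared-normalizer scaling."""
        c = mixture_scale(self.basis, dist)
        class_ll = self.pattern_logliks(dist.omegas, np.full(dist.K, c))
        with np.errstate(divide="ignore"):
            logw = np.where(
                dist.weights > 0, np.log(np.maximum(dist.weights, 1e-300)), -np.inf
            )
        z = class_ll + logw[:, None]
        m = z.max(axis=0)
        return m + np.log(np.exp(z - m[None, :]).sum(axis=0))

    def mixture_loglik(self, dist: SiteClassDistribution) -> float:
        """Total interpolated lnL of the alignment under a mixture."""
        return float(self.mixture_pattern_logliks(dist) @ self.engine.pattern_weights)

    def class_logliks_at_c(self, omegas: np.ndarray, c: float) -> np.ndarray:
        """(K, n_pat) class log-likelihoods at one shared normalizer value."""
        return self.pattern_logliks(np.asarray(omegas, float),
                                    np.full(np.asarray(omegas).size, c))
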