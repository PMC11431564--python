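"""Seeded simulation experiments for statistical validation.

These are the package's calibration/power/recovery studies: each function
simulates replicate alignments with known truth, runs the relevant part of
the analysis, and returns per-replicate results.  Study conditions (taxon
counts, site counts, tree lengths, truth parameters) are fixed here so tests
and scripts exercise the same experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rates import reconstruct_ancestors, slac_site_counts
from .sitemodels import (
    FitConfig,
    dist_m0,
    dist_m1a,
    dist_m2a,
    fit_model,
    lrt,
    make_surface,
)
from .simulate import SimulationSpec, simulate_alignment

#: M1a null truth: strong purifying majority plus a neutral class -- the
#: realistic "no positive selection" condition for a mammalian gene
NULL_TRUTH = dict(p0=0.8, omega0=0.1)

#: selection truth for power runs: 10% of sites at omega 4
POWER_TRUTH = dict(p0=0.5, p1=0.4, omega0=0.2, omega2=4.0)

#: selection truth for parameter-recovery runs: 10% of sites at omega 5
RECOVERY_TRUTH = dict(p0=0.6, p1=0.3, omega0=0.1, omega2=5.0)


def replicate_config(seed: int) -> FitConfig:
    """Desk-scale settings for replicate studies: branch lengths fixed at the
    (known) simulation tree, kappa shared from M0, surface-guided fits."""
    return FitConfig(
        seed=seed,
        polish=False,
        kappa_mode="m0",
        branch_mode="input",
        m0_maxfev=80,
        surface_omega_grid=np.geomspace(1e-4, 50.0, 24),
    )


@dataclass
class LRTReplicate:
    seed: int
    stat: float
    p_value: float


def m7_vs_m8_replicates(
    n_reps: int,
    truth: str = "null",
    n_taxa: int = 12,
    n_sites: int = 300,
    total_length: float = 2.0,
    base_seed: int = 0,
) -> list[LRTReplicate]:
    """M7-vs-M8 LRT over seeded replicates with M1a-family truth."""
    if truth == "null":
        dist = dist_m1a(**NULL_TRUTH)
    elif truth == "power":
        dist = dist_m2a(**POWER_TRUTH)
    elif truth == "m7":
        from .sitemodels import dist_m7

        dist = dist_m7(0.3, 0.7)
    else:
        raise ValueError(f"unknown truth condition {truth!r}")
    out = []
    for rep in range(n_reps):
        seed = base_seed + rep
        spec = SimulationSpec(
            site_classes=dist, n_sites=n_sites, seed=seed, n_taxa=n_taxa,
            total_length=total_length,
        )
        aln, _, tree = simulate_alignment(spec)
        cfg = replicate_config(seed)
        m0 = fit_model(aln, tree, "M0", "F3X4", cfg)
        surface = make_surface(aln, tree, m0, cfg)
        m7 = fit_model(aln, tree, "M7", "F3X4", cfg, m0_fit=m0, surface=surface)
        m8 = fit_model(
            aln, tree, "M8", "F3X4", cfg, m0_fit=m0, null_fit=m7, surface=surface
        )
        res = lrt(m7, m8)
        out.append(LRTReplicate(seed=seed, stat=res.stat, p_value=res.p_value))
    return out


def rejection_rate(reps: list[LRTReplicate], alpha: float = 0.05) -> float:
    return float(np.mean([r.p_value < alpha for r in reps]))


@dataclass
class RecoveryReplicate:
    seed: int
    omega2_hat: float
    p2_hat: float
    lrt_p: float


def m2a_recovery_replicates(
    n_seeds: int = 20,
    n_taxa: int = 16,
    n_sites: int = 400,
    total_length: float = 2.0,
    base_seed: int = 1000,
) -> list[RecoveryReplicate]:
    """End-to-end omega2 recovery under M2a truth (p2=0.1, omega2=5)."""
    dist = dist_m2a(**RECOVERY_TRUTH)
    out = []
    for rep in range(n_seeds):
        seed = base_seed + rep
        spec = SimulationSpec(
            site_classes=dist, n_sites=n_sites, seed=seed, n_taxa=n_taxa,
            total_length=total_length,
        )
        aln, _, tree = simulate_alignment(spec)
        cfg = replicate_config(seed)
        m0 = fit_model(aln, tree, "M0", "F3X4", cfg)
        surface = make_surface(aln, tree, m0, cfg)
        m1a = fit_model(aln, tree, "M1a", "F3X4", cfg, m0_fit=m0, surface=surface)
        m2a = fit_model(
            aln, tree, "M2a", "F3X4", cfg, m0_fit=m0, null_fit=m1a, surface=surface
        )
        res = lrt(m1a, m2a)
        out.append(
            RecoveryReplicate(
                seed=seed,
                omega2_hat=m2a.params["omega2"],
                p2_hat=1.0 - m2a.params["p0"] - m2a.params["p1"],
                lrt_p=res.p_value,
            )
        )
    return out


def slac_direction_replicates(
    omega: float,
    n_reps: int = 20,
    n_taxa: int = 8,
    n_sites: int = 150,
    total_length: float = 1.5,
    base_seed: int = 2000,
) -> list[float]:
    """Gene-average SLAC dN/dS across seeded single-ratio simulations."""
    out = []
    for rep in range(n_reps):
        seed = base_seed + rep
        spec = SimulationSpec(
            site_classes=dist_m0(omega), n_sites=n_sites, seed=seed, n_taxa=n_taxa,
            total_length=total_length,
        )
        aln, _, tree = simulate_alignment(spec)
        cfg = replicate_config(seed)
        m0 = fit_model(aln, tree, "M0", "F3X4", cfg)
        anc = reconstruct_ancestors(aln, tree, m0)
        _, rates = slac_site_counts(aln, tree, anc)
        out.append(rates.avg_dn_ds)
    return out
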