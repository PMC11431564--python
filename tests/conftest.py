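"""Shared fixtures: seeded synthetic datasets and a fast fit configuration.

Session-scoped simulations are reused across test modules so the expensive
pieces (M0 fits, likelihood surfaces) are computed once.
"""

from __future__ import annotations

import pytest

from codonsel.sitemodels import FitConfig, dist_m1a, dist_m2a, fit_model, make_surface
from codonsel.simulate import SimulationSpec, simulate_alignment


def fast_config(seed: int = 0) -> FitConfig:
    """Desk-scale fit settings: branch lengths from the input tree, kappa
    shared from M0, surface-guided optimization without exact polish."""
    return FitConfig(
        seed=seed,
        polish=False,
        kappa_mode="m0",
        branch_mode="input",
        m0_maxfev=120,
    )


@pytest.fixture(scope="session")
def fast_cfg() -> FitConfig:
    return fast_config()


@pytest.fixture(scope="session")
def m1a_sim():
    """Null-model dataset: 80% of sites at omega 0.1, 20% neutral."""
    spec = SimulationSpec(
        site_classes=dist_m1a(0.8, 0.1), n_sites=150, seed=21, n_taxa=8,
        total_length=1.5,
    )
    return simulate_alignment(spec)


@pytest.fixture(scope="session")
def m2a_sim():
    """Selection dataset: 10% of sites at omega 5 on a 12-taxon tree."""
    spec = SimulationSpec(
        site_classes=dist_m2a(0.6, 0.3, 0.1, 5.0), n_sites=200, seed=7, n_taxa=12,
        total_length=2.5,
    )
    return simulate_alignment(spec)


@pytest.fixture(scope="session")
def m2a_m0(m2a_sim, fast_cfg):
    aln, _, tree = m2a_sim
    return fit_model(aln, tree, "M0", "F3X4", fast_cfg)


@pytest.fixture(scope="session")
def m2a_surface(m2a_sim, m2a_m0, fast_cfg):
    aln, _, tree = m2a_sim
    return make_surface(aln, tree, m2a_m0, fast_cfg)


@pytest.fixture(scope="session")
def m2a_fits(m2a_sim, m2a_m0, m2a_surface, fast_cfg):
    """All four mixture fits on the selection dataset (shared surface)."""
    aln, _, tree = m2a_sim
    m1a = fit_model(aln, tree, "M1a", "F3X4", fast_cfg, m0_fit=m2a_m0, surface=m2a_surface)
    m2a = fit_model(
        aln, tree, "M2a", "F3X4", fast_cfg, m0_fit=m2a_m0, null_fit=m1a, surface=m2a_surface
    )
    m7 = fit_model(aln, tree, "M7", "F3X4", fast_cfg, m0_fit=m2a_m0, surface=m2a_surface)
    m8 = fit_model(
        aln, tree, "M8", "F3X4", fast_cfg, m0_fit=m2a_m0, null_fit=m7, surface=m2a_surface
    )
    return {"M0": m2a_m0, "M1a": m1a, "M2a": m2a, "M7": m7, "M8": m8}


@pytest.fixture(scope="session")
def true_positive_sites(m2a_sim) -> set[int]:
    _, truth, _ = m2a_sim
    return set(int(s) - 1 for s in truth[truth.omega > 1]["site"])
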