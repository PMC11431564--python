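"""Per-gene workflow orchestration and study-level aggregation.

``run_gene`` chains the full analysis for one codon alignment: site-model
fits and LRTs under each requested codon-frequency model, the three site
detectors (BEB from M8, FEL, FUBAR) plus SLAC rates, two-of-three consensus
calling in reference coordinates, optional IDR enrichment, and the
free-ratio branch screen.  A gene is labeled positively selected only when
all four LRTs (M1a vs M2a and M7 vs M8, under both F3x4 and F61) are
significant -- the conservative rule.  ``aggregate`` summarizes many gene
reports into study-level counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import CodonAlignment, map_alignment_to_reference
from .annotations import IntervalAnnotation
from .branchmodels import (
    BranchRates,
    SaturationSummary,
    branch_rates_table,
    fit_free_ratio,
    fr_lrt,
    saturation_screen,
)
from .rates import (
    GeneRates,
    SiteScores,
    fel_site_tests,
    fubar_site_posteriors,
    reconstruct_ancestors,
    slac_site_counts,
)
from .report import (
    DEFAULT_CUTOFFS,
    ConsensusCall,
    EnrichmentResult,
    calls_table,
    consensus_calls,
    idr_enrichment,
    selected_calls,
)
from .sitemodels import BEBScores, FitConfig, LRTResult, beb_sites, fit_model, lrt
from .trees import PhyloTree

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Study-level settings for the per-gene workflow."""

    freq_kinds: tuple[str, ...] = ("F3X4", "F61")
    alpha: float = 0.05
    cutoffs: dict = field(default_factory=lambda: dict(DEFAULT_CUTOFFS))
    ds_flags: tuple[float, float] = (0.25, 0.5)
    fit: FitConfig = field(default_factory=FitConfig)
    fubar_grid_size: int = 20
    fubar_samples: int = 10_000
    fubar_method: str = "gibbs"
    seed: int = 0
    run_branches: bool = True
    run_site_detectors: bool = True
    allow_single_freq_label: bool = False

    def __post_init__(self) -> None:
        if not self.freq_kinds:
            raise ValueError("at least one frequency kind required")
        for key, val in self.cutoffs.items():
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"cutoff {key}={val} outside [0, 1]")


@dataclass
class GeneReport:
    gene: str
    fits: dict  # (freq_kind, model) -> ModelFit
    lrts: dict  # (freq_kind, comparison) -> LRTResult
    beb: BEBScores | None = None
    scores: SiteScores | None = None
    gene_rates: GeneRates | None = None
    calls: list[ConsensusCall] = field(default_factory=list)
    enrichment: EnrichmentResult | None = None
    branch_rates: BranchRates | None = None
    fr_lrt_result: LRTResult | None = None
    saturation: SaturationSummary | None = None
    site_map: np.ndarray | None = None
    selected: bool | None = None
    status: dict = field(default_factory=dict)

    @property
    def n_selected_sites(self) -> int:
        return len(selected_calls(self.calls))

    def lrt_table(self) -> pd.DataFrame:
        rows = []
        for (fk, comp), res in sorted(self.lrts.items()):
            rows.append((self.gene, comp, fk, res.stat, res.df, res.p_value))
        return pd.DataFrame(
            rows, columns=["gene", "comparison", "freq_model", "stat", "df", "p_value"]
        )


def run_gene(
    config: RunConfig,
    gene: str,
    aln: CodonAlignment,
    tree: PhyloTree,
    intervals: list[IntervalAnnotation] | None = None,
    protein_length: int | None = None,
) -> GeneReport:
    """Full per-gene analysis; failures are recorded per stage, not raised."""
    tree.validate_against(aln.taxa)
    report = GeneReport(gene=gene, fits={}, lrts={})
    report.site_map = map_alignment_to_reference(aln)
    for fk in config.freq_kinds:
        try:
            m0 = fit_model(aln, tree, "M0", fk, config.fit)
            report.fits[(fk, "M0")] = m0
            m1a = fit_model(aln, tree, "M1a", fk, config.fit, m0_fit=m0)
            m2a = fit_model(aln, tree, "M2a", fk, config.fit, m0_fit=m0, null_fit=m1a)
            m7 = fit_model(aln, tree, "M7", fk, config.fit, m0_fit=m0)
            m8 = fit_model(aln, tree, "M8", fk, config.fit, m0_fit=m0, null_fit=m7)
            for name, fit in (("M1a", m1a), ("M2a", m2a), ("M7", m7), ("M8", m8)):
                report.fits[(fk, name)] = fit
            report.lrts[(fk, "M1a_vs_M2a")] = lrt(m1a, m2a)
            report.lrts[(fk, "M7_vs_M8")] = lrt(m7, m8)
            report.status[f"fits_{fk}"] = "ok"
        except Exception as exc:  # noqa: BLE001 - partial report by contract
            logger.exception("site-model fits failed for %s under %s", gene, fk)
            report.status[f"fits_{fk}"] = f"failed: {exc}"
    primary = config.freq_kinds[0]
    m0 = report.fits.get((primary, "M0"))
    m8 = report.fits.get((primary, "M8"))
    if config.run_site_detectors and m0 is not None:
        try:
            anc = reconstruct_ancestors(aln, tree, m0)
            scores, rates = slac_site_counts(aln, tree, anc, gene=gene)
            scores = fel_site_tests(aln, tree, m0, scores=scores)
            scores = fubar_site_posteriors(
                aln, tree, m0,
                grid_size=config.fubar_grid_size,
                n_samples=config.fubar_samples,
                seed=config.seed,
                method=config.fubar_method,
                scores=scores,
            )
            report.scores = scores
            report.gene_rates = rates
            report.status["site_detectors"] = "ok"
        except Exception as exc:  # noqa: BLE001
            logger.exception("site detectors failed for %s", gene)
            report.status["site_detectors"] = f"failed: {exc}"
    if m8 is not None and report.scores is not None:
        try:
            report.beb = beb_sites(aln, tree, m8, config.fit)
            report.scores.beb_post = report.beb.post_positive
            report.calls = consensus_calls(
                report.beb, report.scores, report.site_map, gene=gene,
                cutoffs=config.cutoffs, intervals=intervals,
            )
            report.status["consensus"] = "ok"
        except Exception as exc:  # noqa: BLE001
            logger.exception("BEB/consensus failed for %s", gene)
            report.status["consensus"] = f"failed: {exc}"
    if intervals is not None and report.calls:
        plen = protein_length or int(report.site_map.max())
        report.enrichment = idr_enrichment(report.calls, intervals, plen, gene=gene)
        report.status["enrichment"] = "ok"
    if config.run_branches and m0 is not None:
        try:
            fr_fit, branch_rates = fit_free_ratio(
                aln, tree, primary, config.fit, m0_fit=m0
            )
            report.branch_rates = branch_rates
            report.fr_lrt_result = fr_lrt(m0, fr_fit, tree)
            report.saturation = saturation_screen(branch_rates, config.ds_flags)
            report.status["branches"] = "ok"
        except Exception as exc:  # noqa: BLE001
            logger.exception("branch models failed for %s", gene)
            report.status["branches"] = f"failed: {exc}"
    report.selected = _label_selected(report, config)
    return report


def _label_selected(report: GeneReport, config: RunConfig) -> bool | None:
    both = {"F3X4", "F61"}.issubset(set(config.freq_kinds))
    if not both and not config.allow_single_freq_label:
        return None
    needed = [
        (fk, comp) for fk in config.freq_kinds for comp in ("M1a_vs_M2a", "M7_vs_M8")
    ]
    if any(key not in report.lrts for key in needed):
        return None
    return all(report.lrts[key].p_value < config.alpha for key in needed)


def write_report(report: GeneReport, out_dir) -> None:
    """Emit the machine-readable gene report (JSON + TSVs)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "gene": report.gene,
        "selected": report.selected,
        "status": report.status,
        "n_selected_sites": report.n_selected_sites,
        "models": {
            f"{fk}:{model}": {
                "lnL": fit.lnL,
                "kappa": fit.kappa_hat,
                "params": {
                    k: v for k, v in fit.params.items() if not isinstance(v, dict)
                },
                "converged": fit.converged,
                "n_starts": fit.n_starts,
            }
            for (fk, model), fit in report.fits.items()
        },
        "lrts": {
            f"{fk}:{comp}": {"stat": r.stat, "df": r.df, "p": r.p_value}
            for (fk, comp), r in report.lrts.items()
        },
    }
    if report.gene_rates is not None:
        payload["slac"] = {
            "avg_dn_ds": report.gene_rates.avg_dn_ds,
            "avg_dn_minus_ds": report.gene_rates.avg_dn_minus_ds,
        }
    if report.enrichment is not None:
        e = report.enrichment
        payload["idr_enrichment"] = {
            "n_sites": e.n_sites, "k_in_idr": e.k_in_idr,
            "idr_fraction": e.idr_fraction, "p_value": e.p_value,
        }
    if report.saturation is not None:
        payload["saturation"] = {
            "n_branches": report.saturation.n_branches,
            "n_over": {str(k): v for k, v in report.saturation.n_over.items()},
        }
    if report.fr_lrt_result is not None:
        payload["fr_lrt"] = {
            "stat": report.fr_lrt_result.stat,
            "df": report.fr_lrt_result.df,
            "p": report.fr_lrt_result.p_value,
        }
    with open(out / f"{report.gene}.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    report.lrt_table().to_csv(out / f"{report.gene}_lrt.tsv", sep="\t", index=False)
    if report.scores is not None:
        report.scores.to_dataframe(report.site_map).to_csv(
            out / f"{report.gene}_sites.tsv", sep="\t", index=False
        )
    if report.calls:
        calls_table(report.calls).to_csv(
            out / f"{report.gene}_consensus.tsv", sep="\t", index=False
        )
    if report.branch_rates is not None:
        branch_rates_table(report.branch_rates).to_csv(
            out / f"{report.gene}_branches.tsv", sep="\t", index=False
        )


@dataclass
class StudySummary:
    n_genes: int
    n_selected: int
    pct_selected: int
    site_counts: dict[str, int]
    pooled_sites: int
    branch_positive_fraction: dict[frozenset, float]


def aggregate(reports: list[GeneReport], trees: dict[str, PhyloTree] | None = None) -> StudySummary:
    """Study-level counts over gene reports.

    The per-branch overlay (fraction of genes with branch omega > 1) is
    aggregated only over branches present, as leaf bipartitions, in every
    gene's tree, restricted to the taxa shared by all genes.
    """
    if not reports:
        raise ValueError("need at least one gene report")
    labeled = [r for r in reports if r.selected is not None]
    n_sel = sum(1 for r in labeled if r.selected)
    site_counts = {r.gene: r.n_selected_sites for r in reports}
    pct = round(100.0 * n_sel / len(labeled)) if labeled else 0
    branch_frac: dict[frozenset, float] = {}
    if trees:
        common = set.intersection(*(set(t.taxa) for t in trees.values()))
        per_gene_sets = {}
        for gene, t in trees.items():
            keys = {}
            for v in t.branch_nodes:
                ls = frozenset(t.leaf_set(v) & common)
                if 0 < len(ls) < len(common):
                    keys[ls] = t.node_labels[v]
            per_gene_sets[gene] = keys
        shared = set.intersection(*(set(k) for k in per_gene_sets.values()))
        for key in shared:
            hits = 0
            n_with = 0
            for r in reports:
                if r.branch_rates is None or r.gene not in per_gene_sets:
                    continue
                label = per_gene_sets[r.gene][key]
                for br in r.branch_rates:
                    if br.branch == label:
                        n_with += 1
                        if np.isfinite(br.omega_hat) and br.omega_hat > 1.0:
                            hits += 1
                        break
            if n_with:
                branch_frac[key] = hits / n_with
    return StudySummary(
        n_genes=len(reports),
        n_selected=n_sel,
        pct_selected=pct,
        site_counts=site_counts,
        pooled_sites=sum(site_counts.values()),
        branch_positive_fraction=branch_frac,
    )
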