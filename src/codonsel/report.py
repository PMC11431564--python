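"""Consensus site calling, IDR enrichment, group comparison, and correlation.

A site is called positively selected only when at least two of the three
detectors agree: BEB posterior >= 0.90, FUBAR posterior >= 0.90, or FEL
p < 0.1 with beta > alpha.  Calls are reported in 1-based reference-protein
coordinates; IDR enrichment is a one-sided binomial test of the number of
calls falling inside (merged) IDR intervals against the IDR coverage
fraction; rate-expression coupling uses Kendall's tau-b (Spearman's rho is
reported alongside); per-site dN - dS distributions are compared across gene
groups by Kruskal-Wallis with Nemenyi post hoc pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import ExpressionRecord, IntervalAnnotation, covered_residues, merge_intervals
from .errors import UsageError
from .rates import GeneRates, POSITIVE, SiteScores
from .sitemodels import BEBScores

DEFAULT_CUTOFFS = {"beb": 0.90, "fubar": 0.90, "fel_p": 0.1}


@dataclass
class ConsensusCall:
    """Per-site consensus decision.

    ``methods`` is the supporting-detector set; ``None`` marks calls imported
    from published site lists where the individual detectors are not known
    (the selected flag is then trusted as given).
    """

    gene: str
    site_ref: int | None  # 1-based reference residue; None if unmapped
    methods: frozenset[str] | None
    selected: bool
    site_aln: int | None = None  # 1-based alignment column, for unmapped sites
    in_idr: bool = False
    in_motif: str | None = None

    def __post_init__(self) -> None:
        if self.methods is not None and self.selected != (len(self.methods) >= 2):
            raise UsageError("selected flag inconsistent with supporting methods")


@dataclass
class EnrichmentResult:
    gene: str
    n_sites: int
    k_in_idr: int
    idr_fraction: float
    p_value: float
    degenerate: bool = False


@dataclass
class GroupCompareResult:
    h_stat: float
    p_value: float
    group_names: list[str]
    pairwise_p: dict[tuple[str, str], float]


@dataclass
class CorrelationResult:
    pairs: list[tuple[str, float, float]]
    tau: float
    tau_p: float
    rho: float
    rho_p: float


# ------------------------------------------------------------- consensus
def consensus_calls(
    beb: BEBScores,
    scores: SiteScores,
    site_map: np.ndarray,
    gene: str = "gene",
    cutoffs: dict | None = None,
    intervals: list[IntervalAnnotation] | None = None,
) -> list[ConsensusCall]:
    """Two-of-three consensus over BEB, FUBAR, and FEL detections.

    FEL counts as a detection only when its direction is positive AND
    p < cutoff.  Sites whose reference map entry is -1 (reference gap) are
    reported with alignment coordinates instead and are excluded from
    enrichment downstream.  Calls are sorted by reference coordinate.
    """
    cut = dict(DEFAULT_CUTOFFS)
    if cutoffs:
        cut.update(cutoffs)
    for key in ("beb", "fubar"):
        if not (0.0 <= cut[key] <= 1.0):
            raise UsageError(f"cutoff {key}={cut[key]} outside [0, 1]")
    if not (0.0 <= cut["fel_p"] <= 1.0):
        raise UsageError(f"cutoff fel_p={cut['fel_p']} outside [0, 1]")
    n_sites = scores.n_sites
    idr_spans = merge_intervals([iv for iv in (intervals or []) if iv.kind == "IDR"])
    motif_ivs = [iv for iv in (intervals or []) if iv.kind != "IDR"]
    calls = []
    for s in range(n_sites):
        methods = set()
        if beb.post_positive[s] >= cut["beb"]:
            methods.add("BEB")
        if (
            scores.fubar_post_positive is not None
            and scores.fubar_post_positive[s] >= cut["fubar"]
        ):
            methods.add("FUBAR")
        if (
            scores.fel_p is not None
            and scores.fel_p[s] < cut["fel_p"]
            and scores.fel_direction[s] == POSITIVE
        ):
            methods.add("FEL")
        if not methods:
            continue
        ref = int(site_map[s]) if site_map[s] > 0 else None
        in_idr = ref is not None and any(a <= ref <= b for a, b in idr_spans)
        motif = None
        if ref is not None:
            for iv in motif_ivs:
                if iv.contains(ref):
                    motif = iv.label or iv.kind
                    break
        calls.append(
            ConsensusCall(
                gene=gene,
                site_ref=ref,
                site_aln=None if ref is not None else s + 1,
                methods=frozenset(methods),
                selected=len(methods) >= 2,
                in_idr=in_idr,
                in_motif=motif,
            )
        )
    calls.sort(key=lambda c: (c.site_ref is None, c.site_ref or 0, c.site_aln or 0))
    return calls


def selected_calls(calls: list[ConsensusCall]) -> list[ConsensusCall]:
    return [c for c in calls if c.selected]


def calls_table(calls: list[ConsensusCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                c.gene,
                c.site_ref if c.site_ref is not None else "",
                c.site_aln if c.site_aln is not None else "",
                ",".join(sorted(c.methods)) if c.methods is not None else "",
                c.selected,
                c.in_idr,
                c.in_motif or "",
            )
            for c in calls
        ],
        columns=["gene", "site_ref", "site_aln", "methods", "selected", "in_idr", "motif"],
    )


# ------------------------------------------------------------ enrichment
def idr_enrichment(
    calls: list[ConsensusCall],
    intervals: list[IntervalAnnotation],
    protein_length: int,
    gene: str = "gene",
) -> EnrichmentResult:
    """One-sided binomial enrichment of selected sites inside merged IDRs.

    p0 is the fraction of the protein covered by IDRs; k counts selected
    sites with a reference coordinate inside an IDR; the p-value is the exact
    binomial upper tail P(X >= k).  With zero mappable selected sites the
    result is returned degenerate with p = 1.
    """
    idrs = [iv for iv in intervals if iv.kind == "IDR"]
    p0 = covered_residues(idrs) / protein_length if protein_length else 0.0
    sel = [c for c in selected_calls(calls) if c.site_ref is not None]
    spans = merge_intervals(idrs)
    k = sum(1 for c in sel if any(a <= c.site_ref <= b for a, b in spans))
    n = len(sel)
    if n == 0:
        return EnrichmentResult(
            gene=gene, n_sites=0, k_in_idr=0, idr_fraction=p0, p_value=1.0,
            degenerate=True,
        )
    # exact upper-tail summation of the binomial pmf
    p = float(stats.binom.sf(k - 1, n, p0)) if k > 0 else 1.0
    return EnrichmentResult(
        gene=gene, n_sites=n, k_in_idr=k, idr_fraction=p0, p_value=min(p, 1.0)
    )


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            (r.gene, r.n_sites, r.k_in_idr, r.idr_fraction, r.p_value, r.degenerate)
            for r in results
        ],
        columns=["gene", "n_sites", "k_in_idr", "idr_fraction", "p_value", "degenerate"],
    )
    tested = ~df["degenerate"]
    df["p_bh"] = np.nan  # Benjamini-Hochberg column, labeled as an extension
    if tested.any():
        from statsmodels.stats.multitest import multipletests

        df.loc[tested, "p_bh"] = multipletests(df.loc[tested, "p_value"], method="fdr_bh")[1]
    return df


# -------------------------------------------------------- group comparison
def group_dn_minus_ds_compare(groups: dict[str, np.ndarray]) -> GroupCompareResult:
    """Kruskal-Wallis over >= 2 groups of per-site dN - dS, plus Nemenyi pairs.

    Rank-based with average ranks for ties; the Nemenyi pairwise p-values use
    the studentized-range distribution on tie-corrected mean-rank differences.
    """
    names = list(groups)
    data = [np.asarray(groups[g], float) for g in names]
    if len(names) < 2 or any(d.size < 5 for d in data):
        raise UsageError("need >= 2 groups with >= 5 sites each")
    if np.unique(np.concatenate(data)).size == 1:
        return GroupCompareResult(
            h_stat=0.0, p_value=1.0, group_names=names,
            pairwise_p={(a, b): 1.0 for i, a in enumerate(names) for b in names[i + 1:]},
        )
    h, p = stats.kruskal(*data)
    # Nemenyi post hoc on mean ranks
    pooled = np.concatenate(data)
    ranks = stats.rankdata(pooled)
    n_tot = pooled.size
    sizes = [d.size for d in data]
    mean_ranks = []
    pos = 0
    for sz in sizes:
        mean_ranks.append(ranks[pos : pos + sz].mean())
        pos += sz
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - (tie_counts**3 - tie_counts).sum() / max(n_tot**3 - n_tot, 1)
    k = len(names)
    pairwise = {}
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(
                (n_tot * (n_tot + 1) / 12.0) * (1.0 / sizes[i] + 1.0 / sizes[j]) * tie_corr
            )
            q = abs(mean_ranks[i] - mean_ranks[j]) / se * np.sqrt(2.0)
            pw = float(stats.studentized_range.sf(q, k, 1e7))
            pairwise[(names[i], names[j])] = min(max(pw, 0.0), 1.0)
    return GroupCompareResult(
        h_stat=float(h), p_value=float(p), group_names=names, pairwise_p=pairwise
    )


# ------------------------------------------------------------ correlation
def rate_expression_correlation(
    gene_rates: list[GeneRates] | dict[str, float],
    expression: list[ExpressionRecord],
    stage: str,
) -> CorrelationResult:
    """Kendall tau-b (with exact p for n <= 8 and no ties) between gene
    dN/dS and log2 fold-change at one meiotic stage; Spearman rho alongside."""
    if isinstance(gene_rates, dict):
        rate_of = dict(gene_rates)
    else:
        rate_of = {r.gene: r.avg_dn_ds for r in gene_rates}
    fc_of = {r.gene: r.log2fc for r in expression if r.stage == stage}
    genes = sorted(set(rate_of) & set(fc_of))
    if len(genes) < 4:
        raise UsageError(f"need >= 4 genes with both values, got {len(genes)}")
    x = np.array([rate_of[g] for g in genes])
    y = np.array([fc_of[g] for g in genes])
    n = len(genes)
    no_ties = np.unique(x).size == n and np.unique(y).size == n
    method = "exact" if (n <= 8 and no_ties) else "asymptotic"
    tau, tau_p = stats.kendalltau(x, y, method=method)
    rho, rho_p = stats.spearmanr(x, y)
    return CorrelationResult(
        pairs=[(g, float(rate_of[g]), float(fc_of[g])) for g in genes],
        tau=float(tau), tau_p=float(tau_p), rho=float(rho), rho_p=float(rho_p),
    )
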