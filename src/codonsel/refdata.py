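"""Bundled reference summary statistics for the 26 mammalian SMC-complex genes.

Three small tables ship with the package: the gene roster with SLAC-average
dN/dS and species counts; the site-model LRT statistics (M1a vs M2a and M7 vs
M8 under both F3x4 and F61 codon frequency models) for the genes where the
positive-selection models were favored; and the consensus positively selected
sites (detected by at least two of BEB, FEL, FUBAR), in 1-based human-protein
coordinates.  They serve as fixed inputs for study-level bookkeeping: re-derived
LRT tail probabilities, consensus site counts, and the fraction of genes
labeled positively selected under the conservative all-four-tests rule.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .report import ConsensusCall
from .sitemodels import chi2_tail

MEIOTIC_COHESINS = ("RAD21L1", "REC8", "SMC1B", "STAG3")


def _read(name: str) -> pd.DataFrame:
    with resources.files("codonsel.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_gene_summary() -> pd.DataFrame:
    """Gene roster: gene, complex, group, n_species, dnds."""
    return _read("smc_genes.tsv")


def load_site_model_tests() -> pd.DataFrame:
    """Per-gene LRT statistics with re-derived chi-square(2) tail p-values.

    ``p_printed`` is kept as the published string (its digit count defines the
    printed precision); ``p_published`` is the float value.
    """
    with resources.files("codonsel.data").joinpath("smc_site_model_tests.tsv").open("r") as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"p_printed": str})
    df["p_published"] = df["p_printed"].astype(float)
    df["p_recomputed"] = [chi2_tail(s, 2) for s in df["stat"]]
    return df


def printed_ulp(text: str) -> float:
    """One unit in the last printed digit of a decimal/scientific literal."""
    s = text.strip().lower()
    if "e" in s:
        mantissa, exponent = s.split("e")
        exp = int(exponent)
    else:
        mantissa, exp = s, 0
    decimals = len(mantissa.split(".")[1]) if "." in mantissa else 0
    return 10.0 ** (exp - decimals)


def load_selected_sites() -> pd.DataFrame:
    """Published consensus selected sites (gene, 1-based residue)."""
    return _read("smc_selected_sites.tsv")


def reference_consensus_calls() -> list[ConsensusCall]:
    """The published site lists expressed in the consensus-call data model.

    The per-site supporting-method sets are not published, so ``methods`` is
    None and the selected flag is carried as given.
    """
    sites = load_selected_sites()
    return [
        ConsensusCall(
            gene=str(r.gene), site_ref=int(r.site), methods=None, selected=True
        )
        for r in sites.itertuples(index=False)
    ]


def consensus_site_counts() -> dict[str, int]:
    """Total consensus sites and the meiotic-cohesin subtotal."""
    calls = reference_consensus_calls()
    total = sum(1 for c in calls if c.selected)
    meiotic = sum(1 for c in calls if c.selected and c.gene in MEIOTIC_COHESINS)
    return {"total": total, "meiotic_cohesins": meiotic}


def label_selected_genes(alpha: float = 0.05) -> set[str]:
    """Genes significant in all four LRTs (both comparisons x both frequency
    models) at level alpha -- the conservative positive-selection label."""
    tests = load_site_model_tests()
    selected = set()
    for gene, sub in tests.groupby("gene"):
        if len(sub) == 4 and (sub["p_recomputed"] < alpha).all():
            selected.add(str(gene))
    return selected


def selected_gene_percentage(alpha: float = 0.05) -> float:
    """Percentage of the 26-gene roster labeled positively selected,
    rounded to the nearest integer percent."""
    n_total = len(load_gene_summary())
    n_sel = len(label_selected_genes(alpha))
    return round(100.0 * n_sel / n_total)
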