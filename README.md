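# codonsel

Codon-model analysis of positive selection in protein-coding genes, built
around the study design used for mammalian SMC-complex (cohesin, condensin,
SMC5/6) genes: site-class dN/dS likelihood models with likelihood-ratio
tests, three per-site selection detectors with conservative consensus
calling, counting-based rates, free-ratio branch analysis, enrichment of
selected sites in intrinsically disordered regions (IDRs), and correlation
of evolutionary rates with meiotic gene expression — plus a fully seeded
synthetic-data generator so every statistical claim can be tested against
known truth.

## Who this is for

Molecular evolutionary biologists who want a scriptable, testable
reimplementation of the standard positive-selection workflow (the kind
usually assembled from codeml and HyPhy runs) for in-frame codon alignments
with a known tree, and methods developers who need a reference
implementation with explicit oracles.

## The models

The core is the Goldman–Yang codon substitution model over the 61 sense
codons: the rate from codon *i* to *j* (single-nucleotide changes only) is
proportional to `pi_j`, times `kappa` for transitions and `omega = dN/dS`
for nonsynonymous changes, with equilibrium frequencies from F3x4 or F61 and
branch lengths in expected substitutions per codon. On top of it:

* **Site-class models** M0, M1a, M2a, M7, M8, fitted by multi-start
  bounded maximum likelihood via Felsenstein pruning. Positive selection is
  tested with 2ΔlnL for M1a vs M2a and M7 vs M8 against chi-square(df = 2)
  (closed form `exp(−stat/2)`); a gene is labeled positively selected only
  when **all four** comparisons (both tests × both frequency models) are
  significant.
* **Per-site detectors:** Bayes empirical Bayes posteriors P(omega > 1)
  under M8 (cutoff 0.90), FUBAR grid-Bayesian posteriors (cutoff 0.90), and
  FEL per-site alpha/beta likelihood tests (p < 0.1, positive direction).
  A site is a selection target only when **at least two** detectors agree.
* **SLAC** counting on marginal-ML ancestral codons for gene-average dN/dS
  and per-site dN − dS.
* **Free-ratio** branch model (one omega per branch) with its LRT
  (df = branches − 1) and a dS saturation screen (dS > 0.25, dS > 0.5).
* **Downstream statistics:** exact binomial IDR enrichment,
  Kruskal–Wallis + Nemenyi group comparison of per-site dN − dS, and
  Kendall tau-b rate–expression correlation.

See `docs/methods.md` for assumptions, parameter defaults, numerical
choices, and known limitations (including a calibration caveat for M7 vs M8
under discrete nulls).

## Worked example

Simulate a gene under positive selection (15% of sites at omega = 6 on an
8-taxon tree of total length 2.5) and run the full workflow:

```sh
codonsel simulate --n-taxa 8 --n-sites 120 --tree-length 2.5 \
    --weights 0.55,0.3,0.15 --omegas 0.1,1.0,6.0 --seed 11 \
    --out-prefix selgene
codonsel run selgene.fasta selgene.nwk --gene selgene \
    --fubar-samples 3000 --seed 11 --out-dir out
```

which prints

```json
{
  "gene": "selgene",
  "selected": true,
  "n_selected_sites": 8,
  "status": {
    "fits_F3X4": "ok",
    "fits_F61": "ok",
    "site_detectors": "ok",
    "consensus": "ok",
    "branches": "ok"
  }
}
```

`selected: true` means all four LRTs rejected their null at 0.05 — here
overwhelmingly (from `out/selgene.json`: M1a vs M2a under F3x4 gives
2ΔlnL = 129.56, p = 7.3e-29; M7 vs M8 under F61 gives 2ΔlnL = 122.07,
p = 3.1e-27). The eight consensus sites in `out/selgene_consensus.tsv`
(e.g. site 6 by {BEB, FUBAR}, sites 21 and 45 by all three detectors) are
all members of the simulation's true omega = 6 class recorded in
`selgene_truth.tsv` — 8 of the 16 truly selected sites pass the
conservative two-of-three rule, and no neutral or purifying site does. The
SLAC gene average dN/dS is 1.03, reflecting the mixture of strong
constraint (omega = 0.1) and strong selection in this synthetic gene.

The same steps are available as library calls (`codonsel.run_gene`,
`codonsel.fit_model`, `codonsel.beb_sites`, ...); the CLI is a thin wrapper.

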