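# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `codonsel`. It is written for users who want to know exactly
what is computed, under which assumptions, and what the synthetic-data tests
do and do not demonstrate about real data.

## Codon substitution model

All analyses use the Goldman–Yang-style codon model over the 61 sense codons
of the standard genetic code, ordered lexicographically over T, C, A, G (the
convention of the major codon-model packages, so matrices are comparable
entry-by-entry). The instantaneous rate from codon *i* to codon *j* is

    q_ij = 0                                  if i and j differ at >1 position
    q_ij = pi_j                               synonymous transversion
    q_ij = kappa * pi_j                       synonymous transition
    q_ij = omega * pi_j                       nonsynonymous transversion
    q_ij = omega * kappa * pi_j               nonsynonymous transition

with equilibrium codon frequencies `pi` given by one of FEQUAL (1/61), F1x4,
F3x4 (position-specific nucleotide frequencies multiplied and renormalized
over sense codons) or F61 (observed codon proportions). Observed — not
ML-estimated — frequencies are used for F3x4/F61. A pseudo-count of 0.1 per
sense codon (F61) or per nucleotide per position (F3x4/F1x4) keeps every
frequency positive on small alignments; the value is a smoothing constant,
not a fitted parameter.

The generator is scaled so that −Σ pi_i q_ii = 1, i.e. branch lengths count
expected substitutions per codon. Because the expected rate is linear in
omega (mu(omega) = muS + omega·muN), scaling constants for arbitrary mixtures
are cheap to compute. Transition probabilities P(t) = exp(Qt) are obtained by
eigendecomposition of the symmetrized matrix Pi^1/2 Q Pi^-1/2, which is exact
and stable for reversible generators; tiny negative entries from rounding are
clipped to zero.

## Likelihood engine

Per-site likelihoods are computed by Felsenstein pruning over the 61-state
space with (i) site-pattern compression — identical columns are computed once
and weighted, bit-transparently re-expanded in all outputs; (ii) per-node
rescaling with log-scale accumulators, which keeps 60+ taxon trees away from
underflow; (iii) a flat partial of 1 over all 61 codons for MISSING states
(any codon containing a gap or ambiguity character; codon-level complete
missingness rather than marginalization over compatible codons). Trees are
held in canonical unrooted form (a basal bifurcation is collapsed on input,
2n−3 branches); the likelihood is computed from an arbitrary rooting, and a
test asserts rooting invariance. The engine is verified against an
exhaustive enumeration oracle (sum over all internal-node state assignments)
on small instances.

Site-class mixtures follow the shared-normalization convention: with classes
(p_k, omega_k), a single constant c = Σ p_k mu(omega_k) scales every class
matrix, so a branch length is the expected substitutions per codon averaged
over classes, and class k traverses branch t at effective length
t·mu(omega_k)/c. The same convention is used by the simulator, so generated
branch lengths and fitted branch lengths live on the same scale.

## Site-class models and fitting

The implemented families are M0 (one ratio), M1a (p0 at omega0<1, rest
neutral), M2a (M1a plus a selection class omega2 ≥ 1), M7 (beta on (0,1),
discretized) and M8 (M7 plus a selection class omega_s ≥ 1). The beta is
discretized into K = 10 equal-probability bins represented by bin medians
(K configurable); medians are numerically stable for extreme shape
parameters. Parity with other implementations' discretization is not
guaranteed and small lnL differences are expected.

Fitting is bounded multi-start local optimization (Nelder–Mead in
transformed coordinates: logits for weights and omega0, logs for kappa and
beta shapes, a scaled logit for omega2/omega_s on [1, 50]). Bounds: omega ≤
50, kappa in [0.01, 100], beta shapes in [0.005, 99]. Starts are a fixed
default plus Latin-hypercube draws from a seeded sampler, so "best of
n_starts" is reproducible; a fit is flagged non-converged when the best two
starts disagree by more than 0.01 lnL units.

M0 optimizes kappa, omega and branch lengths (a global scale first, then
coordinate-wise per-branch Brent sweeps using edge-top partials). The
mixture models fix branch lengths at the M0 estimates — a deliberate
runtime/parity trade-off: other implementations re-optimize lengths per
model, so small lnL differences against them are expected, while LRTs within
this package compare models fitted under identical conditions.

Two implementation details matter for the LRTs:

* **Likelihood surface.** Mixture optimization is guided by a per-site
  log-likelihood surface precomputed on a grid of (omega, c) — 32
  log-spaced omegas in [1e-4, 50] × 10 normalization constants — and
  interpolated with a tensor-product natural bicubic spline (worst observed
  interpolation error ≈ 0.05 lnL on a 300-codon test alignment). The surface
  only steers the optimizer: every reported lnL (and every LRT statistic) is
  re-evaluated exactly by pruning at the chosen parameters, with an optional
  exact polish stage.
* **Nesting guarantee.** The alternative model's candidate set always
  includes the exact embedding of the fitted null (M1a→M2a with p2 = 0,
  M7→M8 with p0 = 1), evaluated exactly. Hence lnL(alt) ≥ lnL(null) holds by
  construction and the LRT statistic is nonnegative before clipping.

LRTs use 2ΔlnL against chi-square with df = 2 for both M1a-vs-M2a and
M7-vs-M8; for df = 2 the tail is the closed form exp(−stat/2). The statistic
is clipped at zero. A gene is labeled positively selected only when all four
comparisons (both tests under both F3x4 and F61) are significant at the
chosen level — the conservative rule.

### Calibration caveat for M7 vs M8 under discrete nulls

Under data generated from M1a (a point mass at omega0 plus a point mass at
exactly 1), the M7-vs-M8 LRT rejects far in excess of its nominal level even
though no site is under positive selection: M7's beta on (0,1) cannot
represent the neutral point mass, while M8's extra class can, so the
statistic measures real misspecification of the null family rather than
sampling noise. This is the classical motivation for the M8a null (beta plus
a fixed omega = 1 class), which is outside this package's scope. The
validation suite documents both facts: under truth drawn from M7 itself the
test is conservative (rejection below nominal), and under M1a truth it is
strongly anti-conservative. Users combining M7-vs-M8 with M1a-vs-M2a — as
the conservative labeling rule does — should treat the latter as the
safeguard against this failure mode.

## BEB site detection

Bayes empirical Bayes site posteriors are computed for a fitted M2a or M8:
mixture parameters are integrated over a uniform prior grid (10 points per
dimension by default — M2a: p0, the p1-share of the remainder, omega0 in
(0,1), omega2 on (1,11]; M8: p0, beta shapes p,q on (0,2], omega_s on
(1,11]), with kappa and branch lengths fixed at their MLEs. P(omega>1) at a
site is the posterior-weighted mass of the selection class; sites at or
above 0.90 are flagged. This is an approximate BEB: the original's exact
grid and priors are not fully published, and the grid here is documented as
the definition. A degenerate single-point grid provably reduces to the
naive empirical Bayes posterior and is evaluated exactly (as is any grid of
at most 50 points; larger grids use the likelihood surface).

## SLAC

Ancestral codons are reconstructed by **marginal** posterior argmax per node
and site under the fitted M0 (ties break toward the lower codon index); this
is a deliberate divergence from joint-ML reconstruction, chosen for per-site
independence and simple oracle testing. Substitutions implied along each
branch are classified synonymous/nonsynonymous; multi-nucleotide changes are
averaged with equal weight over all minimal single-step paths that avoid
stop codons. Opportunity counts per codon follow the standard
mutational-opportunity convention: each position's three alternatives,
stop-excluded with the position's unit weight shared among the remaining
ones, so syn+nonsyn sites sum to 3 per codon; per branch the endpoint
average is used. Per site, dn = observed nonsyn / nonsyn opportunity summed
over branches (ds likewise) and the reported statistic is dn − ds; the gene
average dN/dS is the ratio of the pooled ratios. The per-site one-tailed
"positive" p-value uses the regularized incomplete-beta form of the binomial
upper tail, which extends smoothly to the fractional counts that path
averaging produces. SLAC feeds rates and dn−ds only; it is not part of the
consensus detector trio.

## FEL

Per site, a synonymous rate alpha and nonsynonymous rate beta scale the
synonymous/nonsynonymous parts of the global generator (kappa, frequencies
and branch lengths fixed from the M0 fit; alpha = beta = 1 recovers a
neutral site at the gene's scale). The alternative maximizes (alpha, beta),
the null constrains alpha = beta; 2ΔlnL is referred to chi-square(1), and
the final statistic is evaluated exactly at the optimizer's solutions.
Direction is positive iff beta-hat > alpha-hat; detection for the consensus
rule additionally requires p < 0.1. Invariant sites short-circuit to p = 1.
Measured per-site power at omega = 8 rises from ~0.13 (tree length 3) to a
plateau of ~0.6–0.75 (tree length 12–24): a single codon column simply
carries limited information, consistent with the method's published
behavior.

## FUBAR

Site likelihoods are precomputed on a 20×20 (alpha, beta) grid
(quadratically spaced on [0, 10], denser near zero) and grid weights follow
a symmetric Dirichlet(0.5) prior. The posterior is integrated by a seeded
collapsed Gibbs sampler (per-site cell assignments, then Dirichlet weight
draws; 10,000 sweeps by default with a 20% burn-in), or by an EM point
estimate (`method="em"`) when a deterministic fast path is preferred. The
detector output is the per-site posterior probability that beta > alpha;
0.90 is the consensus cutoff. Posterior stability across seeds is tested to
within 0.05 per site at desk-scale sampler settings.

## Consensus calling and downstream statistics

A site is a positive-selection target only when at least two of {BEB ≥
0.90, FUBAR ≥ 0.90, FEL p < 0.1 with positive direction} agree. Calls are
reported in 1-based residue coordinates of the reference protein (the first
FASTA record unless configured); alignment columns where the reference has a
gap are reported in alignment coordinates and excluded from enrichment.

IDR enrichment is the exact binomial upper tail P(X ≥ k) with success
probability equal to the fraction of the protein covered by merged IDR
intervals (IDRs are intervals ≥ 30 residues; overlaps merged to avoid double
counting). Genes with zero mappable consensus sites are excluded (flagged
degenerate), not silently assigned p = 1. Raw p-values are primary; a
Benjamini–Hochberg column is emitted as a clearly labeled extension.

Group comparison of per-site dn−ds vectors uses Kruskal–Wallis (average
ranks for ties) with Nemenyi post hoc pairwise p-values from the
studentized-range distribution on tie-corrected mean-rank differences.
Rate–expression coupling uses Kendall's tau-b (exact p by enumeration for n
≤ 8 without ties, normal approximation otherwise) with Spearman's rho
reported alongside.

## Branch models

The free-ratio model gives every branch its own omega (shared kappa,
lengths optimized). Each branch's generator is unit-scaled at its own omega,
so a branch length is expected substitutions per codon on that branch.
Optimization is coordinate-wise: per-branch (length, omega) Nelder–Mead with
the rest of the tree summarized by edge-top partials, alternating with a 1-D
kappa update, iterated until the per-sweep lnL gain falls below 1e-4.
Omega is capped at 50 (capped branches flagged); zero-length branches have
undefined omega (flagged, not raised). A two-taxon tree has a single
effective branch, so the free-ratio fit is returned as the relabeled
one-ratio fit. The LRT uses df = branches − 1.

Per-branch dN and dS are read off the scaled generator: expected synonymous
substitutions per codon are t·muS/mu(omega), converted to per-site rates by
the neutral site fractions muS/mu(1) and 1 − muS/mu(1), and likewise for
dN; this makes dN/dS = omega exactly. The saturation screen counts branches
with dS over 0.25 and 0.5 (configurable).

Across genes, the branch overlay (fraction of genes with omega > 1 per
branch) aggregates only branches that appear, as leaf bipartitions over the
taxa common to all genes, in every gene's tree; species-tree reconciliation
beyond that is out of scope.

## Synthetic data

The generator produces every input with known truth and full determinism
(identical spec + seed gives byte-identical files):

* **Alignments.** Site classes are drawn from the mixture weights, root
  codons from pi, and states evolve down the tree with the same
  shared-normalization transition matrices the inference uses. Default
  conditions: Yule topologies (sequential random tip splitting, Exp(1) edge
  lengths rescaled to a requested total length — one interpretable
  divergence knob), F3x4 frequencies from a mildly skewed mammalian-like
  base composition, kappa = 2. Truth tables (per-site class, omega, root
  codon) are written beside alignments.
* **IDR annotations.** Merged intervals ≥ 30 residues covering a requested
  fraction (to within one residue), with selected sites placed inside IDRs
  at a requested odds ratio relative to outside.
* **Expression.** log2 fold-changes rank-coupled to gene omega through a
  Gaussian copula with rho = sin(pi·tau/2), so the expected Kendall tau
  equals the target; tau = ±1 is constructed exactly.

What passing synthetic tests do **not** show about real data: no indels or
alignment error (columns are true homologies by construction), no
recombination, no among-site synonymous rate variation, no compositional
heterogeneity across lineages, and expression values are rank-coupled noise
rather than measured counts. Results on real alignments inherit all the
usual caveats those phenomena introduce.

## Validation studies and problem sizes

The statistical test suite runs seeded replicate studies at desk scale
(sizes chosen as the package's standing validation conditions):

* LRT behavior: 200 replicates of 12 taxa × 300 codons under M1a truth
  (p0 = 0.8, omega0 = 0.1) and 100 replicates of 12 taxa × 250 codons with
  10% of sites at omega = 4 (total tree length 2) for power; 24 replicates
  under M7 truth for null-space calibration.
* Recovery: 20 seeds of 16 taxa × 400 codons under M2a truth (p2 = 0.1,
  omega2 = 5); the criterion is omega2-hat in [3, 8] and a significant
  M1a-vs-M2a LRT in ≥ 90% of seeds.
* SLAC direction: 20 + 20 seeds of 8 taxa × 150 codons at omega 0.1 and 3.
* Replicate fits use the fast configuration: branch lengths fixed at the
  known simulation tree, kappa shared from M0, surface-guided optimization
  without the exact polish stage (the exact evaluation at the optimum is
  always performed).

## Known limitations

* Branch lengths are not re-optimized per site-class model; lnL values are
  therefore not directly comparable to implementations that do.
* BEB is approximate (documented grid, not the original's).
* The M7-vs-M8 test inherits the discrete-null misspecification described
  above; no M8a null is provided.
* FUBAR's Gibbs sampler is desk-scale; posteriors carry Monte-Carlo noise of
  up to ~0.05 at default settings.
* Codon-level missing data only; no marginalization over partially resolved
  codons.
* The free-ratio optimizer is coordinate-wise and can terminate at local
  optima on very flat surfaces; the nesting invariant (FR ≥ one-ratio) is
  still guaranteed because it starts from the one-ratio solution.
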