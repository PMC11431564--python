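"""Synthetic data with known ground truth.

Generates every input the analysis pipeline consumes: codon alignments
evolved under site-class omega mixtures on a known tree, IDR interval
annotations with a controlled fraction of the protein covered and a
controlled enrichment of selected sites inside them, and expression
log2 fold-change vectors with a controlled rank correlation to gene omega.

All outputs are deterministic functions of an explicit integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import CodonAlignment
from .annotations import ExpressionRecord, IntervalAnnotation
from .errors import UsageError, ValidationFailure
from .genetics import NUCS, STANDARD_CODE
from .likelihood import SiteClassDistribution, mixture_scale
from .ratematrix import FreqModel, GY94Basis
from .trees import PhyloTree

#: default position-specific nucleotide frequencies (rows: codon positions,
#: columns: T, C, A, G) -- a mild mammalian-like compositional skew
DEFAULT_BASE_FREQS = np.array(
    [
        [0.22, 0.24, 0.29, 0.25],
        [0.27, 0.23, 0.30, 0.20],
        [0.24, 0.28, 0.22, 0.26],
    ]
)


def pi_from_base_freqs(base_freqs: np.ndarray) -> np.ndarray:
    """F3x4-style sense-codon frequencies from per-position nucleotide freqs."""
    bf = np.asarray(base_freqs, float)
    if bf.shape != (3, 4):
        raise ValidationFailure("base_freqs must be 3x4 (positions x TCAG)")
    bf = bf / bf.sum(axis=1, keepdims=True)
    idx = {n: i for i, n in enumerate(NUCS)}
    pi = np.array(
        [bf[0, idx[c[0]]] * bf[1, idx[c[1]]] * bf[2, idx[c[2]]]
         for c in STANDARD_CODE.sense_codons]
    )
    return pi / pi.sum()


@dataclass
class SimulationSpec:
    """Conditions for one synthetic codon alignment."""

    site_classes: SiteClassDistribution
    n_sites: int
    seed: int
    tree: PhyloTree | None = None
    n_taxa: int = 16
    total_length: float = 2.0
    shape: str = "yule"  # 'yule' | 'balanced'
    kappa: float = 2.0
    base_freqs: np.ndarray = field(default_factory=lambda: DEFAULT_BASE_FREQS.copy())

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValidationFailure("n_sites must be >= 1")
        if self.seed is None:
            raise ValidationFailure("seed is mandatory")


# ------------------------------------------------------------------ trees
def yule_tree(n_taxa: int, total_length: float, seed: int) -> PhyloTree:
    """Random Yule-style topology with Exp(1) edge lengths rescaled to a
    requested total tree length."""
    if n_taxa < 2:
        raise UsageError("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    # nodes: dict id -> (left, right) for internals, None for tips
    children: dict[int, tuple[int, int] | None] = {0: None, 1: None}
    root_kids = (0, 1)
    tips = [0, 1]
    next_id = 2
    while len(tips) < n_taxa:
        k = int(rng.integers(len(tips)))
        tip = tips[k]
        a, b = next_id, next_id + 1
        next_id += 2
        children[tip] = (a, b)
        children[a] = None
        children[b] = None
        tips[k] = a
        tips.append(b)
    # deterministic traversal order for edge-length draws
    order: list[int] = []

    def visit(v: int) -> None:
        order.append(v)
        if children[v] is not None:
            visit(children[v][0])
            visit(children[v][1])

    visit(root_kids[0])
    visit(root_kids[1])
    raw = {v: float(rng.exponential(1.0)) for v in order}
    scale = total_length / sum(raw.values())
    label_counter = [0]
    labels: dict[int, str] = {}

    def name(v: int) -> str:
        if v not in labels:
            label_counter[0] += 1
            labels[v] = f"t{label_counter[0]}"
        return labels[v]

    def newick(v: int) -> str:
        if children[v] is None:
            return f"{name(v)}:{raw[v] * scale:.10g}"
        l, r = children[v]
        return f"({newick(l)},{newick(r)}):{raw[v] * scale:.10g}"

    s = f"({newick(root_kids[0])},{newick(root_kids[1])});"
    return PhyloTree.from_newick_string(s)


def balanced_tree(n_taxa: int, total_length: float) -> PhyloTree:
    """Perfectly balanced topology (n_taxa a power of two), equal edge lengths."""
    if n_taxa < 2 or n_taxa & (n_taxa - 1):
        raise UsageError("balanced trees require n_taxa to be a power of two")
    n_edges = 2 * n_taxa - 2  # rooted-bifurcating edge count before derooting
    el = total_length / n_edges
    counter = [0]

    def build(k: int) -> str:
        if k == 1:
            counter[0] += 1
            return f"t{counter[0]}:{el:.10g}"
        return f"({build(k // 2)},{build(k - k // 2)}):{el:.10g}"

    s = f"({build(n_taxa // 2)},{build(n_taxa - n_taxa // 2)});"
    return PhyloTree.from_newick_string(s)


def tree_for_spec(spec: SimulationSpec) -> PhyloTree:
    if spec.tree is not None:
        return spec.tree
    if spec.shape == "balanced":
        return balanced_tree(spec.n_taxa, spec.total_length)
    return yule_tree(spec.n_taxa, spec.total_length, spec.seed)


# ------------------------------------------------------------- alignments
def _sample_transitions(P: np.ndarray, states: np.ndarray, rng) -> np.ndarray:
    """Sample child states given parent states under transition matrix P."""
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(states.size)
    return (u[:, None] > cum[states]).sum(axis=1).astype(np.int16)


def simulate_alignment(
    spec: SimulationSpec, return_states: bool = False
) -> tuple[CodonAlignment, pd.DataFrame, PhyloTree] | tuple[
    CodonAlignment, pd.DataFrame, PhyloTree, np.ndarray
]:
    """Evolve a codon alignment under a site-class mixture on a tree.

    Returns the alignment, a per-site truth table (1-based site, class index,
    omega, root codon), and the tree used.  Class rate matrices share the
    mixture normalization, so branch lengths are expected substitutions per
    codon averaged over classes.
    """
    tree = tree_for_spec(spec)
    rng = np.random.default_rng(spec.seed)
    dist = spec.site_classes
    pi = pi_from_base_freqs(spec.base_freqs)
    freq = FreqModel("F3X4", pi)
    basis = GY94Basis(spec.kappa, freq)
    c = mixture_scale(basis, dist)
    n_sites = spec.n_sites
    site_class = rng.choice(dist.K, size=n_sites, p=dist.weights)
    root_states = rng.choice(61, size=n_sites, p=pi)
    states = np.empty((tree.n_nodes, n_sites), dtype=np.int16)
    states[tree.root] = root_states
    preorder = [v for v in reversed(tree.postorder) if v != tree.root]
    for k in range(dist.K):
        sel = np.nonzero(site_class == k)[0]
        if sel.size == 0:
            continue
        gen = basis.generator(float(dist.omegas[k]), scaled=True)
        f = basis.mu(float(dist.omegas[k])) / c
        for v in preorder:
            P = gen.P(tree.lengths[v] * f)
            P = P / P.sum(axis=1, keepdims=True)
            states[v, sel] = _sample_transitions(P, states[tree.parent[v], sel], rng)
    taxa = list(tree.taxa)
    codons = states[: tree.n_leaves]
    aln = CodonAlignment(taxa=taxa, codons=codons.copy(), reference_taxon=taxa[0])
    truth = pd.DataFrame(
        {
            "site": np.arange(1, n_sites + 1),
            "class_index": site_class,
            "omega": dist.omegas[site_class],
            "root_codon": [STANDARD_CODE.sense_codons[s] for s in root_states],
        }
    )
    if return_states:
        return aln, truth, tree, states
    return aln, truth, tree


def simulate_branch_alignment(
    tree: PhyloTree,
    omegas_by_label: dict[str, float],
    n_sites: int,
    seed: int,
    kappa: float = 2.0,
    default_omega: float = 0.2,
    base_freqs: np.ndarray | None = None,
) -> CodonAlignment:
    """Evolve an alignment with branch-specific omega (single class per site).

    Each branch evolves under the unit-rate generator of its own omega, so
    branch lengths are expected substitutions per codon on that branch --
    the generative counterpart of the free-ratio model.
    """
    rng = np.random.default_rng(seed)
    pi = pi_from_base_freqs(base_freqs if base_freqs is not None else DEFAULT_BASE_FREQS)
    freq = FreqModel("F3X4", pi)
    basis = GY94Basis(kappa, freq)
    states = np.empty((tree.n_nodes, n_sites), dtype=np.int16)
    states[tree.root] = rng.choice(61, size=n_sites, p=pi)
    preorder = [v for v in reversed(tree.postorder) if v != tree.root]
    for v in preorder:
        om = omegas_by_label.get(tree.node_labels[v], default_omega)
        P = basis.generator(float(om), scaled=True).P(tree.lengths[v])
        P = P / P.sum(axis=1, keepdims=True)
        states[v] = _sample_transitions(P, states[tree.parent[v]], rng)
    taxa = list(tree.taxa)
    return CodonAlignment(
        taxa=taxa, codons=states[: tree.n_leaves].copy(), reference_taxon=taxa[0]
    )


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ------------------------------------------------------------ annotations
def simulate_idr_annotation(
    protein_length: int,
    idr_fraction: float,
    selected_sites: int,
    enrichment_odds: float,
    seed: int,
    protein: str = "synthetic",
) -> tuple[list[IntervalAnnotation], list[int]]:
    """Random merged IDR intervals plus selected-site placements.

    The intervals cover ``idr_fraction`` of the protein (to within one
    residue), each at least 30 residues where feasible, and the given number
    of selected sites are placed inside IDRs with the requested odds relative
    to outside placement.
    """
    if not (0.0 < idr_fraction < 1.0):
        raise UsageError("idr_fraction must be in (0, 1)")
    if enrichment_odds < 1.0:
        raise UsageError("enrichment_odds must be >= 1")
    target = int(round(idr_fraction * protein_length))
    if target < 30:
        raise ValidationFailure(
            f"protein of length {protein_length} cannot host a >=30-residue IDR "
            f"at fraction {idr_fraction}"
        )
    rng = np.random.default_rng(seed)
    max_iv = max(1, target // 60)
    n_iv = int(rng.integers(1, max_iv + 1))
    # random composition of `target` into n_iv parts each >= 30 (stars & bars)
    extra = target - 30 * n_iv
    cuts = np.sort(rng.integers(0, extra + 1, size=n_iv - 1)) if n_iv > 1 else np.array([], int)
    parts = np.diff(np.concatenate([[0], cuts, [extra]]))
    sizes = 30 + parts
    free = protein_length - target
    # interior gaps >= 1; ends may touch the termini
    interior = n_iv - 1
    if free < interior:
        raise ValidationFailure("idr_fraction too high to separate intervals")
    gap_cuts = np.sort(rng.integers(0, free - interior + 1, size=n_iv))
    gaps = np.diff(np.concatenate([[0], gap_cuts, [free - interior]]))
    intervals = []
    pos = 0
    for i, size in enumerate(sizes):
        pos += gaps[i] + (1 if i > 0 else 0)
        start = pos + 1
        end = pos + int(size)
        intervals.append(
            IntervalAnnotation(protein=protein, kind="IDR", start=start, end=end)
        )
        pos = end
    covered = np.concatenate(
        [np.arange(iv.start, iv.end + 1) for iv in intervals]
    )
    uncovered = np.setdiff1d(np.arange(1, protein_length + 1), covered)
    f = covered.size / protein_length
    p_in = enrichment_odds * f / (enrichment_odds * f + (1.0 - f))
    in_pool = list(rng.permutation(covered))
    out_pool = list(rng.permutation(uncovered))
    positions = []
    for _ in range(selected_sites):
        use_in = rng.random() < p_in
        pool = in_pool if (use_in and in_pool) or not out_pool else out_pool
        positions.append(int(pool.pop()))
    return intervals, positions


# ------------------------------------------------------------- expression
def simulate_expression(
    gene_rates: dict[str, float],
    target_tau: float,
    seed: int,
    stage: str = "leptotene_F",
) -> list[ExpressionRecord]:
    """log2 fold-changes rank-coupled to gene omega via a Gaussian copula.

    The copula correlation rho = sin(pi * tau / 2) makes the expected Kendall
    tau of the output equal target_tau; tau = +/-1 is constructed exactly.
    """
    if not (-1.0 <= target_tau <= 1.0):
        raise UsageError("target_tau must be in [-1, 1]")
    genes = sorted(gene_rates)
    if len(genes) < 5:
        raise UsageError("need at least 5 genes")
    rng = np.random.default_rng(seed)
    rates = np.array([gene_rates[g] for g in genes])
    order = np.argsort(np.argsort(rates, kind="stable"), kind="stable")
    n = len(genes)
    normal_scores = (order + 0.5) / n
    from scipy.stats import norm

    x = norm.ppf(normal_scores)
    if abs(target_tau) == 1.0:
        y = np.sign(target_tau) * x + 0.0
    else:
        rho = np.sin(np.pi * target_tau / 2.0)
        y = rho * x + np.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
    return [
        ExpressionRecord(gene=g, stage=stage, log2fc=float(y[i]))
        for i, g in enumerate(genes)
    ]
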