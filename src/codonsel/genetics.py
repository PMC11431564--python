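"""Genetic code, codon state space, and substitution classification.

The 61 sense codons of the standard code form the state space used by every
rate matrix and partial-likelihood vector in the package.  Codons are ordered
lexicographically over the nucleotide order T, C, A, G (TTT, TTC, TTA, TTG,
TCT, ...), the conventional ordering of codon-model software, so that any
61-vector or 61x61 matrix printed here can be compared entry-by-entry with
published matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations, product

import numpy as np
from Bio.Data import CodonTable

NUCS = "TCAG"
#: integer state for a codon that is unresolved (gap or ambiguity)
MISSING = -1

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def is_transition(a: str, b: str) -> bool:
    """True if the nucleotide change a->b is a transition (A<->G or C<->T)."""
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


@dataclass(frozen=True)
class GeneticCode:
    """The codon -> amino-acid map restricted to sense codons.

    Attributes
    ----------
    table_id:
        NCBI translation table identifier (1 = standard code).
    sense_codons:
        The 61 non-stop triplets in fixed T,C,A,G-lexicographic order.
    codon_to_aa:
        Map over all 64 triplets; stop codons map to ``"*"``.
    """

    table_id: int = 1
    sense_codons: tuple[str, ...] = field(init=False)
    stop_codons: frozenset[str] = field(init=False)
    codon_to_aa: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        table = CodonTable.unambiguous_dna_by_id[self.table_id]
        all_codons = ["".join(c) for c in product(NUCS, repeat=3)]
        stops = frozenset(table.stop_codons)
        mapping = {c: ("*" if c in stops else table.forward_table[c]) for c in all_codons}
        object.__setattr__(self, "stop_codons", stops)
        object.__setattr__(self, "codon_to_aa", mapping)
        object.__setattr__(
            self, "sense_codons", tuple(c for c in all_codons if c not in stops)
        )

    @property
    def n_states(self) -> int:
        return len(self.sense_codons)

    def index(self, codon: str) -> int:
        """0-based index of a sense codon in the fixed ordering."""
        return self.sense_codons.index(codon)

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon]


#: module-level standard code instance used throughout
STANDARD_CODE = GeneticCode()

_SENSE = STANDARD_CODE.sense_codons
_CODON_INDEX = {c: i for i, c in enumerate(_SENSE)}
_AA = np.array([STANDARD_CODE.codon_to_aa[c] for c in _SENSE])


def codon_index(codon: str) -> int:
    """Index of a sense codon, or MISSING for anything else (gap, ambiguity, stop)."""
    return _CODON_INDEX.get(codon, MISSING)


def _pair_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    n = len(_SENSE)
    ndiff = np.zeros((n, n), dtype=np.int8)
    transition = np.zeros((n, n), dtype=bool)
    nonsyn = np.zeros((n, n), dtype=bool)
    diff_pos = np.full((n, n), -1, dtype=np.int8)
    for i, ci in enumerate(_SENSE):
        for j, cj in enumerate(_SENSE):
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            ndiff[i, j] = len(diffs)
            nonsyn[i, j] = _AA[i] != _AA[j]
            if len(diffs) == 1:
                k = diffs[0]
                diff_pos[i, j] = k
                transition[i, j] = is_transition(ci[k], cj[k])
    return ndiff, transition, nonsyn, diff_pos


#: pairwise tables over the 61x61 sense-codon pairs
N_DIFF, IS_TRANSITION_PAIR, IS_NONSYN_PAIR, DIFF_POS = _pair_tables()


def count_path_changes(ci: int, cj: int) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) substitution counts from codon ci to cj.

    Single-nucleotide differences are classified directly.  Multi-step pairs are
    averaged with equal weight over all minimal single-step paths that never
    pass through a stop codon.  Identical codons return (0, 0).
    """
    a, b = _SENSE[ci], _SENSE[cj]
    diffs = [k for k in range(3) if a[k] != b[k]]
    if not diffs:
        return 0.0, 0.0
    syn_total = 0.0
    nonsyn_total = 0.0
    n_paths = 0
    for order in permutations(diffs):
        cur = a
        syn = nonsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STANDARD_CODE.stop_codons:
                ok = False
                break
            if STANDARD_CODE.codon_to_aa[cur] == STANDARD_CODE.codon_to_aa[nxt]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            n_paths += 1
            syn_total += syn
            nonsyn_total += nonsyn
    if n_paths == 0:
        # every minimal path crosses a stop codon; fall back to classifying the
        # endpoints position-by-position (cannot happen between sense codons of
        # the standard code for <=2 differences, guarded for completeness)
        syn = sum(
            1 for k in diffs if STANDARD_CODE.codon_to_aa[a] == STANDARD_CODE.codon_to_aa[b]
        )
        return float(syn), float(len(diffs) - syn)
    return syn_total / n_paths, nonsyn_total / n_paths


def _opportunity_tables() -> tuple[np.ndarray, np.ndarray]:
    """Per-codon synonymous/nonsynonymous site counts (mutational opportunity).

    For each codon position, the three single-nucleotide alternatives are
    considered; alternatives creating a stop codon are excluded and the
    position's unit weight is shared equally among the remaining ones.  The
    two counts therefore sum to 3 for every codon.
    """
    n = len(_SENSE)
    syn_sites = np.zeros(n)
    nonsyn_sites = np.zeros(n)
    for i, c in enumerate(_SENSE):
        for pos in range(3):
            alts = [
                c[:pos] + nt + c[pos + 1 :]
                for nt in NUCS
                if nt != c[pos]
            ]
            valid = [a for a in alts if a not in STANDARD_CODE.stop_codons]
            if not valid:  # pragma: no cover - impossible under the standard code
                continue
            w = 1.0 / len(valid)
            for a in valid:
                if STANDARD_CODE.codon_to_aa[a] == STANDARD_CODE.codon_to_aa[c]:
                    syn_sites[i] += w
                else:
                    nonsyn_sites[i] += w
    return syn_sites, nonsyn_sites


#: per-codon mutational-opportunity site counts (sum to 3 per codon)
SYN_SITES, NONSYN_SITES = _opportunity_tables()
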