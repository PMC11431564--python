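"""GY94-style codon rate matrices and transition probabilities.

The instantaneous rate from codon i to codon j (differing at exactly one
nucleotide) is proportional to pi_j, multiplied by kappa for transitions and
by omega for nonsynonymous changes.  Matrices are scaled so that branch
lengths count expected substitutions per codon, and exponentiated through the
symmetrized eigendecomposition Pi^1/2 Q Pi^-1/2, which is numerically stable
because the model is time reversible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import CodonAlignment
from .errors import ContentError, UsageError, ValidationFailure
from .genetics import (
    IS_NONSYN_PAIR,
    IS_TRANSITION_PAIR,
    MISSING,
    N_DIFF,
    NUCS,
    STANDARD_CODE,
)

FREQ_KINDS = ("FEQUAL", "F1X4", "F3X4", "F61")

#: pseudo-count added per sense codon (F61) or per nucleotide (F1x4/F3x4)
#: before renormalisation, to keep all equilibrium frequencies positive on
#: small alignments
PSEUDOCOUNT = 0.1


@dataclass(frozen=True)
class FreqModel:
    """Equilibrium codon frequencies over the 61 sense codons."""

    kind: str
    pi: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in FREQ_KINDS:
            raise ValidationFailure(f"unknown frequency kind {self.kind!r}")
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (61,):
            raise ValidationFailure("pi must be a 61-vector")
        if np.any(pi < 0):
            raise ValidationFailure("negative codon frequency")
        if abs(pi.sum() - 1.0) > 1e-12:
            raise ValidationFailure("codon frequencies must sum to 1")
        object.__setattr__(self, "pi", pi)


def estimate_frequencies(aln: CodonAlignment, kind: str = "F3X4") -> FreqModel:
    """Estimate equilibrium codon frequencies from observed data.

    F61: observed sense-codon proportions with a pseudo-count of
    :data:`PSEUDOCOUNT` per codon.  F3X4: per-codon-position nucleotide
    proportions (same pseudo-count per nucleotide) multiplied and renormalized
    over the 61 sense codons.  F1X4 pools the three positions.  FEQUAL is the
    uniform 1/61 vector.
    """
    if kind not in FREQ_KINDS:
        raise UsageError(f"unknown frequency kind {kind!r}")
    if kind == "FEQUAL":
        return FreqModel(kind, np.full(61, 1.0 / 61.0))
    states = aln.codons[aln.codons != MISSING]
    if states.size == 0:
        raise ContentError("all alignment cells are missing; cannot estimate frequencies")
    if kind == "F61":
        counts = np.bincount(states, minlength=61).astype(float) + PSEUDOCOUNT
        return FreqModel(kind, counts / counts.sum())
    # nucleotide counts per codon position
    nuc_index = {n: i for i, n in enumerate(NUCS)}
    pos_counts = np.full((3, 4), PSEUDOCOUNT)
    for s in states:
        codon = STANDARD_CODE.sense_codons[s]
        for p in range(3):
            pos_counts[p, nuc_index[codon[p]]] += 1
    if kind == "F1X4":
        pooled = pos_counts.sum(axis=0)
        pos_freqs = np.tile(pooled / pooled.sum(), (3, 1))
    else:
        pos_freqs = pos_counts / pos_counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos_freqs[0, nuc_index[c[0]]]
            * pos_freqs[1, nuc_index[c[1]]]
            * pos_freqs[2, nuc_index[c[2]]]
            for c in STANDARD_CODE.sense_codons
        ]
    )
    return FreqModel(kind, pi / pi.sum())


class GY94Basis:
    """Precomputed single-nucleotide exchange rates for fixed (kappa, pi).

    The raw generator decomposes as Q_raw(omega) = Rs + omega * Rn on the
    off-diagonal, where Rs holds synonymous and Rn nonsynonymous rates, so the
    expected substitution rate is linear in omega: mu(omega) = muS + omega*muN.
    """

    def __init__(self, kappa: float, freq: FreqModel):
        if kappa <= 0:
            raise UsageError("kappa must be positive")
        self.kappa = float(kappa)
        self.freq = freq
        pi = freq.pi
        single = N_DIFF == 1
        base = np.where(single, np.where(IS_TRANSITION_PAIR, kappa, 1.0), 0.0)
        base = base * pi[None, :]
        self.Rs = np.where(~IS_NONSYN_PAIR, base, 0.0)
        self.Rn = np.where(IS_NONSYN_PAIR, base, 0.0)
        self.muS = float(pi @ self.Rs.sum(axis=1))
        self.muN = float(pi @ self.Rn.sum(axis=1))
        self._eig_cache: dict[float, "TransitionGenerator"] = {}

    def mu(self, omega: float) -> float:
        """Expected substitutions per codon per unit raw time at this omega."""
        return self.muS + float(omega) * self.muN

    def q_raw(self, omega: float) -> np.ndarray:
        Q = self.Rs + float(omega) * self.Rn
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def generator(self, omega: float, scaled: bool = True) -> "TransitionGenerator":
        """Eigendecomposed generator at a given omega (unit mean rate if scaled)."""
        key = (float(omega), bool(scaled))
        gen = self._eig_cache.get(key)
        if gen is None:
            Q = self.q_raw(omega)
            if scaled:
                Q = Q / self.mu(omega)
            gen = TransitionGenerator(Q, self.freq.pi)
            self._eig_cache[key] = gen
        return gen


class TransitionGenerator:
    """P(t) = exp(Qt) for a reversible generator, via symmetrized eigh."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        self.Q = Q
        self.pi = pi
        sqrt_pi = np.sqrt(pi)
        B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        B = 0.5 * (B + B.T)  # symmetrize away rounding noise
        w, U = np.linalg.eigh(B)
        self._w = w
        self._left = U / sqrt_pi[:, None]
        self._right = U.T * sqrt_pi[None, :]

    def P(self, t: float) -> np.ndarray:
        if t < 0:
            raise UsageError("branch length must be nonnegative")
        P = (self._left * np.exp(self._w * t)) @ self._right
        np.clip(P, 0.0, None, out=P)
        return P

    def P_batch(self, ts: np.ndarray) -> np.ndarray:
        """Transition matrices for a vector of branch lengths, shape (B, 61, 61)."""
        E = np.exp(self._w[None, :] * np.asarray(ts, float)[:, None])
        P = np.matmul(self._left[None, :, :] * E[:, None, :], self._right)
        np.clip(P, 0.0, None, out=P)
        return P


@dataclass(frozen=True)
class CodonRateMatrix:
    """A fully scaled GY94 generator (unit expected substitutions per codon)."""

    kappa: float
    omega: float
    freq: FreqModel
    Q: np.ndarray
    basis: GY94Basis = field(repr=False, default=None)

    @property
    def pi(self) -> np.ndarray:
        return self.freq.pi


def build_Q(kappa: float, omega: float, freq: FreqModel) -> CodonRateMatrix:
    """GY94 rate matrix scaled so branch lengths are substitutions per codon."""
    if omega < 0:
        raise UsageError("omega must be nonnegative")
    basis = GY94Basis(kappa, freq)
    Q = basis.q_raw(omega) / basis.mu(omega)
    return CodonRateMatrix(kappa=float(kappa), omega=float(omega), freq=freq, Q=Q, basis=basis)


def transition_matrix(rate_matrix: CodonRateMatrix, t: float) -> np.ndarray:
    """P(t) = exp(Qt); rows sum to 1, tiny negative entries are clipped to 0."""
    gen = TransitionGenerator(rate_matrix.Q, rate_matrix.pi)
    return gen.P(t)
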