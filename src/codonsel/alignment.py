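"""Codon alignment container and FASTA I/O.

An in-frame coding alignment is stored as a taxa x codon-site matrix of
indices into the 61 sense codons; any codon containing a gap or ambiguity
character is collapsed to the MISSING state (no marginalisation over
compatible codons).  Site coordinates are reported against a designated
reference taxon in 1-based ungapped protein coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .errors import AlignmentError, ContentError, LookupFailure
from .genetics import MISSING, STANDARD_CODE, codon_index

logger = logging.getLogger(__name__)


@dataclass
class CodonAlignment:
    """Aligned coding sequences over the 61-codon state space.

    Attributes
    ----------
    taxa:
        Unique sequence names, in input order.
    codons:
        Integer matrix of shape (n_taxa, n_sites); entries are sense-codon
        indices or :data:`codonsel.genetics.MISSING`.
    reference_taxon:
        Taxon whose ungapped protein coordinates are used in reports.
    raw:
        Original nucleotide strings, preserved for faithful round-trips.
    """

    taxa: list[str]
    codons: np.ndarray
    reference_taxon: str
    raw: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon names in alignment")
        if self.reference_taxon not in self.taxa:
            raise LookupFailure(
                f"reference taxon {self.reference_taxon!r} not among alignment taxa"
            )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return int(self.codons.shape[1])

    def row(self, taxon: str) -> np.ndarray:
        try:
            return self.codons[self.taxa.index(taxon)]
        except ValueError as exc:
            raise LookupFailure(f"unknown taxon {taxon!r}") from exc

    def subset_sites(self, sites: np.ndarray) -> "CodonAlignment":
        """New alignment restricted to the given 0-based site indices."""
        return CodonAlignment(
            taxa=list(self.taxa),
            codons=self.codons[:, sites],
            reference_taxon=self.reference_taxon,
            raw=[],
        )


def _encode_sequence(name: str, seq: str) -> tuple[list[int], int]:
    states: list[int] = []
    n_partial_gaps = 0
    for k in range(0, len(seq), 3):
        codon = seq[k : k + 3].upper()
        idx = codon_index(codon)
        if idx == MISSING:
            if codon in STANDARD_CODE.stop_codons:
                raise ContentError(
                    f"in-frame stop codon {codon} in taxon {name!r} at codon position {k // 3 + 1}"
                )
            if codon != "---" and any(c not in "ACGT" for c in codon):
                n_partial_gaps += 1
        states.append(idx)
    return states, n_partial_gaps


def read_codon_fasta(path, reference_taxon: str | None = None) -> CodonAlignment:
    """Read a codon-aligned FASTA file.

    Codons containing any non-ACGT character (gaps, N, IUPAC ambiguity) map to
    MISSING; a fully gapped triple ``---`` maps to MISSING silently, while
    mixed gap/base triples are counted and logged.  An in-frame stop codon in
    any sequence raises :class:`ContentError`.  The reference taxon defaults
    to the first record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no sequences in {path}")
    names = [r.id for r in records]
    seqs = [str(r.seq) for r in records]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise AlignmentError(f"sequences have unequal lengths {sorted(lengths)} in {path}")
    (length,) = lengths
    if length % 3 != 0:
        raise AlignmentError(f"alignment length {length} is not divisible by 3")
    rows = []
    for name, seq in zip(names, seqs):
        states, n_partial = _encode_sequence(name, seq)
        if n_partial:
            logger.warning(
                "taxon %s: %d codons with mixed gap/ambiguity characters set to MISSING",
                name,
                n_partial,
            )
        rows.append(states)
    ref = reference_taxon if reference_taxon is not None else names[0]
    return CodonAlignment(
        taxa=names,
        codons=np.asarray(rows, dtype=np.int16),
        reference_taxon=ref,
        raw=seqs,
    )


def write_codon_fasta(aln: CodonAlignment, path) -> None:
    """Write the alignment back to FASTA, preserving original strings if kept."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, name in enumerate(aln.taxa):
            if aln.raw:
                seq = aln.raw[i]
            else:
                seq = "".join(
                    STANDARD_CODE.sense_codons[c] if c != MISSING else "---"
                    for c in aln.codons[i]
                )
            fh.write(f">{name}\n{seq}\n")


def map_alignment_to_reference(aln: CodonAlignment) -> np.ndarray:
    """Map each alignment column to a 1-based reference protein residue.

    Returns an integer vector of length n_sites; entries are residue positions
    in the ungapped reference protein, or -1 where the reference row is
    MISSING.  The mapping is strictly increasing over the non-negative entries.
    """
    ref_row = aln.row(aln.reference_taxon)
    out = np.full(aln.n_sites, -1, dtype=np.int64)
    residue = 0
    for col in range(aln.n_sites):
        if ref_row[col] != MISSING:
            residue += 1
            out[col] = residue
    return out


def reference_to_column(site_map: np.ndarray) -> dict[int, int]:
    """Inverse of :func:`map_alignment_to_reference`: residue -> 0-based column."""
    return {int(r): c for c, r in enumerate(site_map) if r > 0}
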