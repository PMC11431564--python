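"""Interval annotations (IDRs, motifs, NLS) and expression tables.

Intervals are 1-based inclusive residue ranges on a reference protein, the
coordinate convention used for all site reporting.  IDRs follow the usual
operational definition of consecutive disordered stretches of at least 30
residues.  Expression records hold per-gene log2 fold-changes of meiotic vs
pre-meiotic stages of mouse gametogenesis.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ValidationFailure

INTERVAL_KINDS = ("IDR", "MOTIF", "NLS", "PARSE")
EXPRESSION_STAGES = (
    "leptotene_F",
    "pachytene_F",
    "leptotene_zygotene_M",
    "pachytene_M",
)

#: minimum length for an interval of kind IDR
MIN_IDR_LENGTH = 30


@dataclass(frozen=True)
class IntervalAnnotation:
    protein: str
    kind: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in INTERVAL_KINDS:
            raise ValidationFailure(f"unknown interval kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise ValidationFailure(
                f"invalid interval [{self.start}, {self.end}] for {self.protein}"
            )
        if self.kind == "IDR" and self.end - self.start + 1 < MIN_IDR_LENGTH:
            raise ValidationFailure(
                f"IDR interval [{self.start}, {self.end}] shorter than "
                f"{MIN_IDR_LENGTH} residues"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, residue: int) -> bool:
        return self.start <= residue <= self.end


@dataclass(frozen=True)
class ExpressionRecord:
    gene: str
    stage: str
    log2fc: float

    def __post_init__(self) -> None:
        if self.stage not in EXPRESSION_STAGES:
            raise ValidationFailure(f"unknown stage {self.stage!r}")


def read_intervals(path, protein_length: int | None = None) -> list[IntervalAnnotation]:
    """Read a TSV with columns protein, kind, start, end, label."""
    df = pd.read_csv(path, sep="\t", dtype={"protein": str, "kind": str, "label": str})
    required = {"protein", "kind", "start", "end"}
    if not required.issubset(df.columns):
        raise ValidationFailure(f"interval table must have columns {sorted(required)}")
    out = []
    for rec in df.itertuples(index=False):
        label = getattr(rec, "label", "") or ""
        if isinstance(label, float):  # NaN from an empty cell
            label = ""
        iv = IntervalAnnotation(
            protein=rec.protein, kind=rec.kind, start=int(rec.start), end=int(rec.end),
            label=str(label),
        )
        if protein_length is not None and iv.end > protein_length:
            raise ValidationFailure(
                f"interval end {iv.end} exceeds protein length {protein_length} "
                f"for {iv.protein}"
            )
        out.append(iv)
    return out


def write_intervals(intervals: list[IntervalAnnotation], path) -> None:
    df = pd.DataFrame(
        [(iv.protein, iv.kind, iv.start, iv.end, iv.label) for iv in intervals],
        columns=["protein", "kind", "start", "end", "label"],
    )
    df.to_csv(path, sep="\t", index=False)


def merge_intervals(intervals: list[IntervalAnnotation]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent intervals into disjoint (start, end) pairs."""
    if not intervals:
        return []
    spans = sorted((iv.start, iv.end) for iv in intervals)
    merged = [spans[0]]
    for s, e in spans[1:]:
        ls, le = merged[-1]
        if s <= le + 1:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


def covered_residues(intervals: list[IntervalAnnotation]) -> int:
    return sum(e - s + 1 for s, e in merge_intervals(intervals))


def read_expression(path) -> list[ExpressionRecord]:
    """Read a TSV with columns gene, stage, log2fc; an empty table is allowed."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "stage", "log2fc"}
    if not required.issubset(df.columns):
        raise ValidationFailure(f"expression table must have columns {sorted(required)}")
    records = [
        ExpressionRecord(gene=str(r.gene), stage=str(r.stage), log2fc=float(r.log2fc))
        for r in df.itertuples(index=False)
    ]
    seen = set()
    for r in records:
        key = (r.gene, r.stage)
        if key in seen:
            raise ValidationFailure(f"duplicate expression record for {key}")
        seen.add(key)
    return records


def write_expression(records: list[ExpressionRecord], path) -> None:
    df = pd.DataFrame(
        [(r.gene, r.stage, r.log2fc) for r in records],
        columns=["gene", "stage", "log2fc"],
    )
    df.to_csv(path, sep="\t", index=False)
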