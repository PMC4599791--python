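"""AT-content and interval statistics for genomes and annotations.

AT content is ``100 * (A + T) / (A + C + G + T)`` over the scoped bases;
N bases are excluded from both numerator and denominator.  Percentages
of genome, by contrast, use the N-inclusive genome length as the
denominator.  Reported values are rounded half-up to one decimal; full
precision is kept internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .io import Feature, GenomeRecord


def round1(value: float) -> float:
    """Round half-up to one decimal (the reporting convention)."""
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), ROUND_HALF_UP))


@dataclass
class IntervalSet:
    """Disjoint sorted 1-based inclusive intervals over one genome."""

    genome_len: int
    circular: bool
    intervals: list[tuple[int, int]]

    @property
    def total_bp(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)

    def gather(self, sequence: str) -> str:
        return "".join(sequence[s - 1 : e] for s, e in self.intervals)


@dataclass
class CompositionSummary:
    total_bp: int
    percent_of_genome: float
    at_percent: float


def at_content(sequence: str, rounded: bool = False) -> float:
    """AT percentage of a sequence; N excluded from the denominator."""
    seq = sequence.upper()
    at = seq.count("A") + seq.count("T")
    acgt = at + seq.count("C") + seq.count("G")
    if acgt == 0:
        raise ValueError("no non-N bases in scope")
    pct = 100.0 * at / acgt
    return round1(pct) if rounded else pct


def at_content_of(record: GenomeRecord, intervals: IntervalSet,
                  rounded: bool = False) -> float:
    return at_content(intervals.gather(record.sequence), rounded)


def interval_length(start: int, end: int, circular: bool = False,
                    genome_len: int | None = None) -> int:
    """Length of a 1-based inclusive interval; ``end < start`` wraps the
    origin on circular genomes."""
    if end >= start:
        return end - start + 1
    if not circular:
        raise ValueError(f"end {end} < start {start} on a linear record")
    if genome_len is None:
        raise ValueError("genome_len required for a wrapped interval")
    return genome_len - start + 1 + end


def _flatten_cds(record: GenomeRecord) -> list[tuple[int, int]]:
    spans = []
    for f in record.features:
        if f.key == "CDS":
            spans.extend(f.intervals)
    return spans


def merge_intervals(spans: list[tuple[int, int]], genome_len: int,
                    circular: bool) -> IntervalSet:
    """Normalize to a disjoint sorted union (strand-blind)."""
    spans = sorted(spans)
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return IntervalSet(genome_len, circular, merged)


def complement_intervals(ivs: IntervalSet) -> IntervalSet:
    """Genome minus the interval set, wrap-aware only through its inputs
    (wrap features arrive as two linear intervals, so plain linear
    complement is exact)."""
    out: list[tuple[int, int]] = []
    pos = 1
    for s, e in ivs.intervals:
        if s > pos:
            out.append((pos, s - 1))
        pos = max(pos, e + 1)
    if pos <= ivs.genome_len:
        out.append((pos, ivs.genome_len))
    return IntervalSet(ivs.genome_len, ivs.circular, out)


def intergenic_regions(record: GenomeRecord) -> tuple[IntervalSet, CompositionSummary]:
    """The intergenic complement of the CDS union and its composition.

    Intergenic is defined against the union of all CDS features
    regardless of strand; overlapping CDS count once.
    """
    spans = _flatten_cds(record)
    if not spans:
        raise ValueError(f"record {record.id!r} has no CDS features")
    cds_union = merge_intervals(spans, len(record), record.circular)
    inter = complement_intervals(cds_union)
    total = inter.total_bp
    seq = inter.gather(record.sequence)
    summary = CompositionSummary(
        total_bp=total,
        percent_of_genome=round1(100.0 * total / len(record)),
        at_percent=round1(at_content(seq)) if seq else 0.0,
    )
    return inter, summary
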