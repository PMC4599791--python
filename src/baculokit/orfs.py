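"""ORF calling on (circular) genomes and polh-first renumbering.

Baculovirus genomes are conventionally numbered with *polh* (polyhedrin)
as ORF 1 in clockwise orientation.  :func:`renumber_polh_first`
implements that convention: the genome origin is conceptually rotated so
polh starts at position 1 on the plus strand (the sequence is
reverse-complemented first if polh lies on the minus strand) and serial
ids are reassigned clockwise.

The caller scans all six reading frames; on circular records frames
continue across the origin.  For each stop codon only the longest
upstream ATG-initiated ORF (the 5'-most ATG after the previous in-frame
stop) is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from Bio.Seq import Seq

from .io import GenomeRecord, reverse_complement

log = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")
DEFAULT_MIN_LENGTH_NT = 150  # 50 codons, common baculovirus annotation floor
DEFAULT_START_CODONS = frozenset({"ATG"})


@dataclass(frozen=True)
class OrfCall:
    """A predicted coding region, stop codon included.

    ``start``/``end`` are 1-based inclusive genome coordinates; on a
    circular record an origin-spanning ORF has ``end < start``.  The ORF
    reads start->end on '+' and end->start on '-'.
    """

    start: int
    end: int
    strand: str
    frame: int
    length_nt: int
    name: str = ""

    @property
    def protein_length(self) -> int:
        return self.length_nt // 3 - 1

    @property
    def wraps(self) -> bool:
        return self.end < self.start


@dataclass
class OrfTable:
    """ORFs with serial ids after polh-first renumbering.

    ``orfs[0]`` is ORF 1 (polh).  Coordinates are in the rotated,
    plus-oriented frame of reference.
    """

    orfs: list[OrfCall]
    genome_len: int
    polh_id: int = 1

    @property
    def forward_count(self) -> int:
        return sum(1 for o in self.orfs if o.strand == "+")

    @property
    def reverse_count(self) -> int:
        return sum(1 for o in self.orfs if o.strand == "-")

    def serial_of(self, name: str) -> int:
        for i, o in enumerate(self.orfs, start=1):
            if o.name == name:
                return i
        raise KeyError(name)


@dataclass(frozen=True)
class AminoAcidChange:
    cds_position: int
    codon_index: int
    ref_residue: str
    alt_residue: str

    @property
    def synonymous(self) -> bool:
        return self.ref_residue == self.alt_residue


def _scan_strand(coding: str, genome_len: int, circular: bool,
                 min_length_nt: int, start_codons: frozenset[str]):
    """Yield (coding_start mod n, length) 0-based ORF spans on one coding
    strand, applying the longest-per-stop rule.

    Circular sequences are scanned doubled so every stop codon is seen
    once with its full upstream context; candidates are keyed by the stop
    codon's genome position and the contextful (hence longest) candidate
    wins.
    """
    n = genome_len
    text = coding + coding if circular else coding
    best: dict[int, tuple[int, int, bool]] = {}  # stop mod n -> (a, len, ctx)
    for offset in range(3):
        atg: int | None = None
        seen_stop = False
        for i in range(offset, len(text) - 2, 3):
            codon = text[i : i + 3]
            if codon in STOP_CODONS:
                if atg is not None:
                    length = i + 3 - atg
                    if min_length_nt <= length <= n:
                        key = i % n
                        prev = best.get(key)
                        if prev is None or (seen_stop, length) > (prev[2], prev[1]):
                            best[key] = (atg % n, length, seen_stop)
                atg = None
                seen_stop = True
            elif codon in start_codons and atg is None:
                atg = i
    for a, length, _ctx in best.values():
        yield a, length


def find_orfs(record: GenomeRecord, min_length_nt: int = DEFAULT_MIN_LENGTH_NT,
              start_codons: frozenset[str] = DEFAULT_START_CODONS) -> list[OrfCall]:
    """Call ORFs in all six frames of ``record``.

    ``min_length_nt`` counts the stop codon and must be a positive
    multiple of 3 (>= 6).  Returns calls sorted by start coordinate on
    the plus-strand numbering; overlapping ORFs are all reported.
    """
    if min_length_nt < 6 or min_length_nt % 3:
        raise ValueError("min_length_nt must be >= 6 and a multiple of 3")
    n = len(record)
    if n < min_length_nt:
        return []
    calls: list[OrfCall] = []
    seq = record.sequence
    for strand, coding in (("+", seq), ("-", reverse_complement(seq))):
        for a, length in _scan_strand(coding, n, record.circular,
                                      min_length_nt, start_codons):
            if strand == "+":
                start = a + 1
                end = (a + length - 1) % n + 1
            else:
                # revcomp index p maps to genome position n - p (1-based)
                start = (n - a - length) % n + 1
                end = (n - a - 1) % n + 1
            calls.append(OrfCall(start, end, strand, a % 3, length))
    calls.sort(key=lambda o: (o.start, o.end, o.strand))
    return calls


def _transform_calls(orfs: list[OrfCall], genome_len: int,
                     flip: bool, shift: int) -> list[OrfCall]:
    """Map ORF coordinates through an optional reverse-complement then a
    rotation placing old position ``shift + 1`` at 1."""
    n = genome_len
    out = []
    for o in orfs:
        start, end, strand = o.start, o.end, o.strand
        if flip:
            start, end = n - end + 1, n - start + 1
            strand = "-" if strand == "+" else "+"
        start = (start - shift - 1) % n + 1
        end = (end - shift - 1) % n + 1
        out.append(replace(o, start=start, end=end, strand=strand))
    return out


def renumber_polh_first(orfs: list[OrfCall], polh_locator: str | int,
                        genome_len: int) -> OrfTable:
    """Renumber ORFs with polh as ORF 1 in clockwise orientation.

    ``polh_locator`` is either an ORF name or a 1-based genome coordinate
    falling inside the polh ORF.  Exactly one ORF must match.
    """
    if isinstance(polh_locator, str):
        hits = [o for o in orfs if o.name == polh_locator]
    else:
        pos = int(polh_locator)

        def contains(o: OrfCall) -> bool:
            if not o.wraps:
                return o.start <= pos <= o.end
            return pos >= o.start or pos <= o.end

        hits = [o for o in orfs if contains(o)]
    if len(hits) != 1:
        raise ValueError(
            f"polh locator {polh_locator!r} matched {len(hits)} ORFs: "
            + ", ".join(f"{o.name or '?'}@{o.start}" for o in hits)
        )
    polh = hits[0]
    flip = polh.strand == "-"
    n = genome_len
    anchor = n - polh.end + 1 if flip else polh.start
    shift = anchor - 1
    polh_index = orfs.index(polh)
    moved = _transform_calls(orfs, n, flip, shift)
    polh_moved = moved[polh_index]
    # clockwise order from polh; polh itself breaks any tie at position 1
    moved.sort(key=lambda o: (o.start, o is not polh_moved, o.end))
    assert moved[0].start == 1 and moved[0].strand == "+"
    return OrfTable(orfs=moved, genome_len=n)


def strand_counts(table: OrfTable) -> tuple[int, int]:
    """(forward, reverse) ORF counts; they sum to the table size."""
    return table.forward_count, table.reverse_count


def orf_calls_from_record(record: GenomeRecord) -> list[OrfCall]:
    """Turn annotated CDS features into :class:`OrfCall` objects (used when
    the annotation comes from a GenBank record rather than the caller)."""
    calls = []
    for f in record.features:
        if f.key != "CDS":
            continue
        length = f.length()
        wrap = len(f.intervals) == 2 and f.intervals[0][1] == len(record)
        start = f.intervals[0][0]
        end = f.intervals[-1][1]
        frame = (start - 1) % 3 if f.strand == "+" else (len(record) - end) % 3
        calls.append(OrfCall(start, end, f.strand, frame, length, name=f.name))
    return calls


def apply_substitution(cds_sequence: str, cds_position: int,
                       alt_base: str) -> AminoAcidChange:
    """Amino-acid effect of one nucleotide substitution inside a CDS.

    ``cds_position`` is 1-based from the first base of the start codon;
    the codon index is ``ceil(cds_position / 3)``.
    """
    cds = cds_sequence.upper()
    alt = alt_base.upper()
    if not 1 <= cds_position <= len(cds):
        raise ValueError(f"position {cds_position} outside CDS of length {len(cds)}")
    if len(cds) % 3:
        raise ValueError("CDS length is not a multiple of 3")
    ref = cds[cds_position - 1]
    if alt == ref:
        raise ValueError(f"alternative base {alt} equals the reference base")
    codon_index = (cds_position + 2) // 3
    codon_start = (codon_index - 1) * 3
    ref_codon = cds[codon_start : codon_start + 3]
    alt_codon = (
        ref_codon[: (cds_position - 1) % 3]
        + alt
        + ref_codon[(cds_position - 1) % 3 + 1 :]
    )
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    return AminoAcidChange(cds_position, codon_index, ref_aa, alt_aa)
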