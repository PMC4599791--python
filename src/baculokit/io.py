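"""Genome records, features, and the standard formats around them.

Coordinate model
----------------
All coordinates in this package are 1-based and inclusive at both ends
(GenBank convention).  A feature that spans the origin of a circular
genome is encoded as exactly two intervals: the first ends at the genome
length, the second starts at 1.  GFF3 output keeps the same convention
natively, so a round trip through :func:`write_gff3` is lossless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.SeqFeature import CompoundLocation

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: GenBank feature keys carried into the object model; everything else is
#: dropped with a debug log line.
MODELED_KEYS = ("CDS", "repeat_region", "misc_feature")


@dataclass
class Feature:
    """A located genome feature (CDS, repeat_region or misc_feature).

    ``intervals`` is an ordered list of ``(start, end)`` pairs, 1-based
    inclusive.  Origin-spanning features on circular genomes carry two
    intervals; all other features carry one.
    """

    key: str
    intervals: list[tuple[int, int]]
    strand: str = "+"
    qualifiers: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.key not in MODELED_KEYS:
            raise ValueError(f"unsupported feature key {self.key!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for start, end in self.intervals:
            if start > end:
                raise ValueError(f"interval start {start} > end {end}")

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[-1][1]

    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)

    @property
    def name(self) -> str:
        for key in ("gene", "locus_tag", "product"):
            if key in self.qualifiers:
                return self.qualifiers[key]
        return ""


@dataclass
class GenomeRecord:
    """A (possibly circular) nucleotide sequence with typed features."""

    id: str
    sequence: str
    circular: bool = False
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"record {self.id!r} contains illegal symbols {sorted(bad)}"
            )
        n = len(self.sequence)
        for feat in self.features:
            for start, end in feat.intervals:
                if start < 1 or end > n:
                    raise ValueError(
                        f"feature {feat.key} {feat.intervals} outside [1, {n}] "
                        f"in record {self.id!r}"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Sequence of the 1-based inclusive interval, wrapping the origin
        when ``end < start`` on a circular record."""
        n = len(self.sequence)
        if not (1 <= start <= n and 1 <= end <= n):
            raise ValueError(f"interval ({start}, {end}) outside [1, {n}]")
        if end >= start:
            return self.sequence[start - 1 : end]
        if not self.circular:
            raise ValueError("wrapped interval on a linear record")
        return self.sequence[start - 1 :] + self.sequence[:end]

    def feature_sequence(self, feat: Feature) -> str:
        """Strand-aware spliced sequence of a feature."""
        s = "".join(self.fetch(a, b) for a, b in feat.intervals)
        return reverse_complement(s) if feat.strand == "-" else s


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def rotate_record(record: GenomeRecord, shift: int) -> GenomeRecord:
    """Rotate a circular genome so that old position ``shift + 1`` becomes
    position 1, shifting every feature accordingly."""
    if not record.circular:
        raise ValueError("only circular records can be rotated")
    n = len(record)
    shift %= n
    seq = record.sequence[shift:] + record.sequence[:shift]

    def move(pos: int) -> int:
        return (pos - shift - 1) % n + 1

    feats = []
    for f in record.features:
        intervals: list[tuple[int, int]] = []
        for a, b in f.intervals:
            na, nb = move(a), move(b)
            if na <= nb:
                intervals.append((na, nb))
            else:  # the interval now spans the new origin
                intervals.append((na, n))
                intervals.append((1, nb))
        # merge intervals that became contiguous across the old origin
        merged: list[tuple[int, int]] = []
        for a, b in intervals:
            if merged and merged[-1][1] + 1 == a:
                merged[-1] = (merged[-1][0], b)
            else:
                merged.append((a, b))
        feats.append(Feature(f.key, merged, f.strand, dict(f.qualifiers)))
    return GenomeRecord(record.id, seq, True, feats)


def _normalize(raw: str, record_id: str) -> str:
    seq = raw.upper()
    bad = sum(1 for c in seq if c not in VALID_BASES)
    if bad:
        log.warning("record %s: %d non-ACGTN symbols replaced by N", record_id, bad)
        seq = "".join(c if c in VALID_BASES else "N" for c in seq)
    return seq


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a (multi-record) FASTA file.

    Lowercase is normalized to uppercase and any symbol outside ACGTN is
    mapped to N with a logged warning count.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _normalize(str(rec.seq), rec.id)
        if not seq:
            raise ValueError(f"record {rec.id!r} in {path} has zero length")
        records.append(GenomeRecord(rec.id, seq, circular=False))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def read_genbank(path: str | Path) -> GenomeRecord:
    """Read one GenBank flat file into a :class:`GenomeRecord`.

    The circular flag is taken from the LOCUS line topology.  CDS and
    repeat_region features are parsed with strand and join() locations; a
    ``join(a..L, 1..b)`` on a circular record becomes a two-interval wrap
    feature.  Other feature keys are ignored.
    """
    try:
        rec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ValueError(f"{path}: malformed GenBank record "
                         f"(missing ORIGIN block or terminator?): {exc}") from exc
    try:
        raw = str(rec.seq)
    except Exception as exc:  # undefined Seq => no ORIGIN block
        raise ValueError(f"{path}: GenBank record has no ORIGIN sequence") from exc
    if not raw:
        raise ValueError(f"{path}: GenBank record has no ORIGIN sequence")
    seq = _normalize(raw, rec.id)
    circular = rec.annotations.get("topology", "linear") == "circular"
    n = len(seq)

    features: list[Feature] = []
    for f in rec.features:
        if f.type not in ("CDS", "repeat_region"):
            log.debug("ignoring %s feature at %s", f.type, f.location)
            continue
        strand = "-" if f.location.strand == -1 else "+"
        parts = (
            f.location.parts
            if isinstance(f.location, CompoundLocation)
            else [f.location]
        )
        intervals = sorted(
            (int(p.start) + 1, int(p.end)) for p in parts
        )
        name = f.qualifiers.get("gene", f.qualifiers.get("locus_tag", ["?"]))[0]
        for a, b in intervals:
            if a < 1 or b > n:
                raise ValueError(
                    f"{path}: feature {f.type} {name} location {a}..{b} "
                    f"outside sequence of length {n}"
                )
        # canonical wrap encoding: (x, n) then (1, y)
        if len(intervals) == 2 and intervals[0] == (1, intervals[0][1]):
            if intervals[1][1] == n:
                intervals = [intervals[1], intervals[0]]
        quals = {k: v[0] for k, v in f.qualifiers.items() if v}
        features.append(Feature(f.type, intervals, strand, quals))
    return GenomeRecord(rec.id, seq, circular, features)


_GFF_SOURCE = "baculokit"


def write_gff3(record: GenomeRecord, path: str | Path) -> None:
    """Write the record's features as GFF3 (1-based inclusive, native).

    Wrap features are emitted as two lines sharing one ID.
    """
    path = Path(path)
    lines = ["##gff-version 3", f"##sequence-region {record.id} 1 {len(record)}"]
    for i, feat in enumerate(record.features, start=1):
        fid = f"{record.id}.{feat.key}.{i}"
        attrs = f"ID={fid}"
        if feat.name:
            attrs += f";Name={feat.name}"
        for a, b in feat.intervals:
            lines.append(
                "\t".join(
                    [
                        record.id,
                        _GFF_SOURCE,
                        feat.key,
                        str(a),
                        str(b),
                        ".",
                        feat.strand,
                        ".",
                        attrs,
                    ]
                )
            )
    path.write_text("\n".join(lines) + "\n")


def read_gff3_features(path: str | Path) -> list[Feature]:
    """Parse features back from a GFF3 file written by :func:`write_gff3`.

    Lines sharing an ID are re-joined into one multi-interval feature.
    """
    by_id: dict[str, Feature] = {}
    order: list[str] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        key, start, end, strand, attrs = cols[2], int(cols[3]), int(cols[4]), cols[6], cols[8]
        fid = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv).get("ID", attrs)
        if fid in by_id:
            by_id[fid].intervals.append((start, end))
        else:
            by_id[fid] = Feature(key, [(start, end)], strand)
            order.append(fid)
    return [by_id[f] for f in order]
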