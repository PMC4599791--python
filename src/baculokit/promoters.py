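"""Promoter-motif classification in the upstream window of each ORF.

Baculovirus promoters are conventionally screened in the 150 bp
immediately 5' of the start codon, on the ORF's coding strand: a TATA
box marks an early (host-RNA-polymerase-II) promoter and a DTAAG box
(D = A/G/T), containing the canonical late transcription start TAAG,
marks a late promoter.  An ORF with both motifs is classed "both", with
neither "none".  No distance constraint is imposed within the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import iupac
from .io import GenomeRecord, reverse_complement
from .orfs import OrfCall

DEFAULT_WINDOW_NT = 150
DEFAULT_EARLY_MOTIF = "TATA"
DEFAULT_LATE_MOTIF = "DTAAG"


@dataclass(frozen=True)
class PromoterConfig:
    window_nt: int = DEFAULT_WINDOW_NT
    early_motif: str = DEFAULT_EARLY_MOTIF
    late_motif: str = DEFAULT_LATE_MOTIF

    def __post_init__(self) -> None:
        if self.window_nt < max(len(self.early_motif), len(self.late_motif)):
            raise ValueError("window shorter than the motifs")


@dataclass
class PromoterCall:
    """Classification of one ORF's upstream window.

    ``hits`` holds ``(motif, offset, matched)`` tuples where offset 1 is
    the base immediately preceding the start codon (offsets count the
    motif's 3'-most base, moving upstream).
    """

    orf: OrfCall
    klass: str
    hits: list[tuple[str, int, str]] = field(default_factory=list)
    truncated_window: bool = False


def upstream_window(record: GenomeRecord, orf: OrfCall,
                    window_nt: int = DEFAULT_WINDOW_NT) -> tuple[str, bool]:
    """The coding-strand sequence 5' of the start codon, 5'->3', ending at
    the base immediately before the ATG.

    Returns ``(window, truncated)``; on a linear record a window running
    off the sequence end is truncated and flagged.
    """
    n = len(record)
    truncated = False
    if orf.strand == "+":
        hi = orf.start - 1          # last window position (may be 0)
        lo = hi - window_nt + 1
        if lo < 1:
            if record.circular:
                lo = (lo - 1) % n + 1
                return record.fetch(lo, (hi - 1) % n + 1), False
            lo, truncated = 1, True
        if hi < 1:
            return "", True
        return record.fetch(lo, hi), truncated
    # minus strand: upstream lies 3' of `end` in genome coordinates
    lo = orf.end + 1
    hi = lo + window_nt - 1
    if hi > n:
        if record.circular:
            return reverse_complement(record.fetch((lo - 1) % n + 1,
                                                   (hi - 1) % n + 1)), False
        hi, truncated = n, True
    if lo > n:
        return "", True
    return reverse_complement(record.fetch(lo, hi)), truncated


def classify_window(window: str, config: PromoterConfig = PromoterConfig()
                    ) -> tuple[str, list[tuple[str, int, str]]]:
    """Classify a bare upstream window string (5'->3', coding strand)."""
    w = len(window)
    hits: list[tuple[str, int, str]] = []
    early = late = False
    for motif, tag in ((config.early_motif, "early"), (config.late_motif, "late")):
        m = len(motif)
        for i in iupac.find_motif(window, motif):
            offset = w - (i + m) + 1  # 1 = base just before the start codon
            hits.append((motif, offset, window[i : i + m]))
            if tag == "early":
                early = True
            else:
                late = True
    if early and late:
        klass = "both"
    elif early:
        klass = "early"
    elif late:
        klass = "late"
    else:
        klass = "none"
    hits.sort(key=lambda h: h[1])
    return klass, hits


def classify_promoter(record: GenomeRecord, orf: OrfCall,
                      config: PromoterConfig = PromoterConfig()) -> PromoterCall:
    """Classify one ORF's promoter as early / late / both / none."""
    window, truncated = upstream_window(record, orf, config.window_nt)
    klass, hits = classify_window(window, config)
    return PromoterCall(orf, klass, hits, truncated_window=truncated)
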