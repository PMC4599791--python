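"""Tandem-repeat discovery and homologous-region (hr) classification.

Baculovirus genomes carry three kinds of repeated loci: homologous
regions (*hrs*) built from tandem copies of a ~66 bp element whose core
is a ~30 bp imperfect palindrome, non-palindromic (*non-hr*) repeat
arrays, and low-complexity A/C-rich runs.  This module detects tandem
arrays with a built-in exhaustive detector, summarizes each array as a
strict IUPAC consensus, scores imperfect palindrome cores, and counts
element copies with the convention that a truncated terminal element
counts as one copy.

Detector rule
-------------
An array of period ``p`` is a maximal chain of consecutive ``p``-blocks
in which every adjacent block pair differs at no more than
``floor(max_divergence * p)`` positions.  Every period in
``[min_period, max_period]`` and every phase is examined (the scan is
vectorized but exhaustive, not seeded), and overlapping candidates are
resolved by more copies, then lower divergence, then smaller start.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import iupac

GAP = "-"


@dataclass(frozen=True)
class RepeatConfig:
    min_period: int = 10
    max_period: int = 80
    min_copies: int = 3          # 2 suffices for A/C-rich runs
    min_copies_ac: int = 2
    max_divergence: float = 0.15
    ambiguity_threshold: float = 0.25
    core_len: int = 30
    max_core_mismatch: int = 4
    trunc_min_fraction: float = 0.5

    def count_max_mismatches(self, period: int) -> int:
        return math.ceil(self.max_divergence * period)


@dataclass
class RepeatElement:
    """One tandem array: its copies, period and strict consensus."""

    copies: list[tuple[int, int, bool]]  # (start, end, is_truncated), 1-based
    period: int
    consensus: str
    mean_divergence: float

    @property
    def span(self) -> tuple[int, int]:
        return self.copies[0][0], self.copies[-1][1]

    @property
    def n_copies(self) -> int:
        return len(self.copies)


@dataclass
class RepeatRegion:
    name: str
    klass: str                   # hr | non_hr | ac_rich
    span: tuple[int, int]
    element: RepeatElement
    palindrome: tuple[int, int] | None = None  # (core offset 0-based, mismatches)


# ---------------------------------------------------------------------------
# tandem array detection


def _chain_arrays(ok: np.ndarray, period: int, min_copies: int):
    """Maximal chains over stride ``period`` in the adjacency mask."""
    m = len(ok)
    if m <= 0:
        return
    prev = np.zeros(m, dtype=bool)
    prev[period:] = ok[:-period]
    starts = np.flatnonzero(ok & ~prev)
    for s in starts:
        k = int(s)
        copies = 1
        while k < m and ok[k]:
            copies += 1
            k += period
        if copies >= min_copies:
            yield int(s), copies


def find_tandem_arrays(sequence: str,
                       min_period: int = 10,
                       max_period: int = 80,
                       min_copies: int = 3,
                       max_divergence: float = 0.15,
                       ambiguity_threshold: float = 0.25,
                       trunc_min_fraction: float | None = None) -> list[RepeatElement]:
    """Detect tandem arrays under the adjacency rule described above.

    Returns non-overlapping :class:`RepeatElement` objects (full copies
    only; truncated terminal copies are handled by :func:`scan_copies`).
    When ``trunc_min_fraction`` is given, overlap resolution counts a
    valid truncated terminal copy toward each candidate's copy total,
    which makes the in-phase reading of an array that ends in a partial
    element outrank its rotated alternatives.
    """
    if min_period > max_period:
        raise ValueError("min_period > max_period")
    if min_copies < 2:
        raise ValueError("min_copies must be >= 2")
    seq = sequence.upper()
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    candidates: list[tuple[int, int, int]] = []  # (start0, period, copies)
    for p in range(min_period, min(max_period, (n - 1) // 2) + 1):
        thr = math.floor(max_divergence * p)
        diff = (arr[: n - p] != arr[p:]).astype(np.int32)
        csum = np.concatenate(([0], np.cumsum(diff)))
        ham = csum[p:] - csum[: n - 2 * p + 1]  # ham[s] over block pair at s
        ok = ham <= thr
        for s, copies in _chain_arrays(ok, p, min_copies):
            candidates.append((s, p, copies))
    elements = [_build_element(seq, s, p, c, ambiguity_threshold)
                for s, p, c in candidates]
    return _resolve_overlaps(elements, seq, trunc_min_fraction)


def _build_element(seq: str, start0: int, period: int, copies: int,
                   ambiguity_threshold: float) -> RepeatElement:
    copy_seqs = [seq[start0 + k * period : start0 + (k + 1) * period]
                 for k in range(copies)]
    consensus = strict_consensus(copy_seqs, ambiguity_threshold)
    div = float(np.mean([
        sum(not iupac.compatible(c, k) for c, k in zip(cp, consensus)) / period
        for cp in copy_seqs
    ]))
    intervals = [(start0 + k * period + 1, start0 + (k + 1) * period, False)
                 for k in range(copies)]
    return RepeatElement(intervals, period, consensus, div)


def _effective_copies(el: RepeatElement, seq: str,
                      trunc_min_fraction: float | None) -> int:
    if trunc_min_fraction is None:
        return el.n_copies
    partial = _terminal_partial(seq, el.span[1], el.consensus,
                                math.ceil(0.15 * el.period),
                                trunc_min_fraction)
    return el.n_copies + (partial is not None)


def _resolve_overlaps(elements: list[RepeatElement], seq: str,
                      trunc_min_fraction: float | None = None
                      ) -> list[RepeatElement]:
    ranked = sorted(
        elements,
        key=lambda e: (-_effective_copies(e, seq, trunc_min_fraction),
                       e.mean_divergence, e.span[0], e.period),
    )
    chosen: list[RepeatElement] = []
    for el in ranked:
        s, e = el.span
        if all(e < c.span[0] or s > c.span[1] for c in chosen):
            chosen.append(el)
    chosen.sort(key=lambda el: el.span)
    return chosen


def _terminal_partial(seq: str, after: int, consensus: str,
                      max_mismatches: int, trunc_min_fraction: float
                      ) -> tuple[int, int] | None:
    """Longest valid truncated-element match starting right after position
    ``after`` (1-based end of the last full copy); pro-rata mismatch
    budget.  Returns (length, mismatches) or None."""
    period = len(consensus)
    i = after  # 0-based index of the first base past the full copies
    min_partial = math.ceil(trunc_min_fraction * period)
    longest = min(period - 1, len(seq) - i)
    for ell in range(longest, min_partial - 1, -1):
        budget = math.floor(max_mismatches * ell / period)
        mm = _mismatches(seq[i : i + ell], consensus[:ell])
        if mm <= budget:
            return ell, mm
    return None


# ---------------------------------------------------------------------------
# consensus and palindrome


def strict_consensus(copies: list[str], ambiguity_threshold: float = 0.25) -> str:
    """Column-wise minimal IUPAC code over aligned copies.

    Per column, the code covers every base whose frequency among non-gap
    symbols reaches ``ambiguity_threshold``; if no base reaches it, the
    code covers all observed bases.  Truncated copies are padded with
    ``-`` (N is treated as uninformative, like a gap).
    """
    if len(copies) < 2:
        raise ValueError("need at least two copies")
    width = max(len(c) for c in copies)
    if width == 0:
        raise ValueError("zero-column input")
    rows = [c.upper().ljust(width, GAP) for c in copies]
    out = []
    for j in range(width):
        col = [r[j] for r in rows if r[j] not in (GAP, "N")]
        if not col:
            out.append("N")
            continue
        total = len(col)
        # copies may themselves carry IUPAC codes (consensus of consensuses);
        # a code contributes to every base it covers
        counts = {b: sum(b in iupac.CODE_TO_BASES[c] for c in col)
                  for b in "ACGT"}
        kept = {b for b, c in counts.items()
                if c and c / total >= ambiguity_threshold}
        if not kept:
            kept = set().union(*(iupac.CODE_TO_BASES[c] for c in col))
        out.append(iupac.code_for(kept))
    return "".join(out)


def palindrome_core(consensus: str, core_len: int = 30,
                    max_mismatch: int = 4) -> tuple[int, int] | None:
    """Best imperfect-palindrome window of ``core_len`` in the consensus.

    A position pair (i, core_len-1-i) mismatches when the IUPAC base set
    at i does not intersect the complement of the set at its mirror.
    Returns ``(offset, mismatches)`` for the lowest-mismatch window
    (leftmost on ties) or None when every window exceeds
    ``max_mismatch``.
    """
    if core_len % 2:
        raise ValueError("core_len must be even")
    if core_len > len(consensus):
        raise ValueError("core_len longer than the consensus")
    best: tuple[int, int] | None = None
    for off in range(len(consensus) - core_len + 1):
        window = consensus[off : off + core_len]
        mm = sum(
            not iupac.compatible(window[i],
                                 iupac.complement_code(window[core_len - 1 - i]))
            for i in range(core_len // 2)
        )
        if best is None or mm < best[1]:
            best = (off, mm)
    if best is not None and best[1] <= max_mismatch:
        return best
    return None


# ---------------------------------------------------------------------------
# classification and copy counting

_AC_CODES = frozenset("ACM")


def classify_region(element: RepeatElement,
                    rules: RepeatConfig = RepeatConfig(),
                    name: str = "") -> RepeatRegion:
    """Classify a tandem array as hr / non_hr / ac_rich.

    A/C-rich means the consensus alphabet is within {A, C, M}; otherwise
    the array is an hr exactly when an imperfect palindrome core of
    ``rules.core_len`` with at most ``rules.max_core_mismatch``
    mismatches exists in the consensus.
    """
    cons = element.consensus
    if set(cons) <= _AC_CODES:
        return RepeatRegion(name, "ac_rich", element.span, element)
    pal = None
    if rules.core_len <= len(cons):
        pal = palindrome_core(cons, rules.core_len, rules.max_core_mismatch)
    klass = "hr" if pal is not None else "non_hr"
    return RepeatRegion(name, klass, element.span, element, palindrome=pal)


def _mismatches(text: str, consensus: str) -> int:
    return sum(not iupac.compatible(c, k) for c, k in zip(text, consensus))


def scan_copies(region_sequence: str, consensus: str,
                max_mismatches: int | None = None,
                trunc_min_fraction: float = 0.5) -> list[tuple[int, int, bool]]:
    """Greedy left-to-right scan for consensus-compatible copies.

    Full windows advance by one period on a match; a terminal partial
    match covering at least ``trunc_min_fraction`` of the consensus is
    reported once with its truncation flag set ("every truncated element
    counts as one").  Mismatch budgets for partials scale pro rata.
    """
    if not consensus:
        raise ValueError("empty consensus")
    period = len(consensus)
    if max_mismatches is None:
        max_mismatches = math.ceil(0.15 * period)
    seq = region_sequence.upper()
    n = len(seq)
    hits: list[tuple[int, int, bool]] = []
    i = 0
    while i + period <= n:
        if _mismatches(seq[i : i + period], consensus) <= max_mismatches:
            hits.append((i + 1, i + period, False))
            i += period
        else:
            i += 1
    partial = _terminal_partial(seq, i, consensus, max_mismatches,
                                trunc_min_fraction)
    if partial is not None:
        hits.append((i + 1, i + partial[0], True))
    return hits


def count_copies(region_sequence: str, consensus: str,
                 max_mismatches: int | None = None,
                 trunc_min_fraction: float = 0.5) -> int:
    """Number of element copies in a region, truncated terminal included."""
    return len(scan_copies(region_sequence, consensus, max_mismatches,
                           trunc_min_fraction))


def compare_hr_consensuses(regions: list[RepeatRegion]
                           ) -> tuple[np.ndarray, str]:
    """Pairwise compatible-position identity of hr consensuses, plus the
    merged strict consensus across regions."""
    if len(regions) < 2:
        raise ValueError("need at least two hr regions")
    conss = [r.element.consensus for r in regions]
    width = len(conss[0])
    if any(len(c) != width for c in conss):
        raise ValueError("consensus lengths differ; pad them first")
    k = len(conss)
    mat = np.eye(k)
    for a in range(k):
        for b in range(a + 1, k):
            ident = sum(iupac.compatible(x, y)
                        for x, y in zip(conss[a], conss[b])) / width
            mat[a, b] = mat[b, a] = ident
    merged = "".join(
        iupac.code_for(set().union(*(iupac.CODE_TO_BASES[c[j]] for c in conss)))
        for j in range(width)
    )
    return mat, merged


# ---------------------------------------------------------------------------
# full pipeline


def find_repeat_regions(sequence: str,
                        config: RepeatConfig = RepeatConfig()) -> list[RepeatRegion]:
    """Detect, classify and name all repeat regions of a genome.

    Arrays are detected down to two copies, classified, and then
    filtered: non-A/C-rich regions need ``config.min_copies`` copies.
    Each kept region is rescanned with :func:`scan_copies` to pick up a
    truncated terminal element.  Regions are named hr1.. in genomic
    order, non-hr and A-C rich by class.
    """
    seq = sequence.upper()
    elements = find_tandem_arrays(
        seq, config.min_period, config.max_period,
        min_copies=min(config.min_copies, config.min_copies_ac),
        max_divergence=config.max_divergence,
        ambiguity_threshold=config.ambiguity_threshold,
        trunc_min_fraction=config.trunc_min_fraction,
    )
    regions: list[RepeatRegion] = []
    for el in elements:
        region = classify_region(el, config)
        needed = (config.min_copies_ac if region.klass == "ac_rich"
                  else config.min_copies)
        if el.n_copies < needed:
            continue
        # extend by one period to catch a truncated terminal copy
        s, e = el.span
        stop = min(len(seq), e + el.period - 1)
        hits = scan_copies(seq[s - 1 : stop], el.consensus,
                           config.count_max_mismatches(el.period),
                           config.trunc_min_fraction)
        el.copies = [(a + s - 1, b + s - 1, t) for a, b, t in hits]
        region.span = (el.copies[0][0], el.copies[-1][1])
        regions.append(region)
    regions.sort(key=lambda r: r.span)
    hr_i = 0
    for r in regions:
        if r.klass == "hr":
            hr_i += 1
            r.name = r.name or f"hr{hr_i}"
        elif r.klass == "non_hr":
            r.name = r.name or "non-hr"
        else:
            r.name = r.name or "A-C rich"
    return regions
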