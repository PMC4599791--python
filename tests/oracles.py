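"""Independent brute-force oracles used to cross-check the library.

Everything here is written for clarity over speed and deliberately does
not share code with the implementation under test.
"""

from __future__ import annotations

import math

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "M": "AC", "K": "GT", "W": "AT", "S": "CG",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
STOPS = {"TAA", "TAG", "TGA"}


def orf_enumerate(sequence: str, circular: bool, min_len: int) -> set:
    """Every ORF by direct enumeration of (position, strand) pairs,
    keeping the 5'-most ATG per stop codon."""
    n = len(sequence)

    def revcomp(s: str) -> str:
        return "".join(COMP[c] for c in reversed(s))

    out = set()
    for strand in "+-":
        text = sequence if strand == "+" else revcomp(sequence)
        doubled = text + text

        def codon(p: int) -> str | None:
            if p + 3 <= n:
                return text[p : p + 3]
            if not circular:
                return None
            return doubled[p : p + 3]

        best: dict[int, int] = {}  # stop position mod n -> max length
        for a in range(n):
            if codon(a) != "ATG":
                continue
            p, length = a, None
            while True:
                c = codon(p)
                if c is None:
                    break
                if c in STOPS:
                    length = p + 3 - a
                    break
                p += 3
                if circular and p - a >= n:
                    break
                if not circular and p + 3 > n:
                    break
            if length is None or length > n or length < min_len:
                continue
            stop_mod = (a + length - 3) % n
            if length > best.get(stop_mod, 0):
                best[stop_mod] = length
        for stop_mod, length in best.items():
            a = (stop_mod + 3 - length) % n
            if strand == "+":
                start, end = a + 1, (a + length - 1) % n + 1
            else:
                start = (n - a - length) % n + 1
                end = (n - a - 1) % n + 1
            out.add((start, end, strand, length))
    return out


def translate_codon(codon: str) -> str:
    from Bio.Data.CodonTable import standard_dna_table

    if codon in STOPS:
        return "*"
    return standard_dna_table.forward_table[codon]


def palindrome_scan(consensus: str, core_len: int) -> list[tuple[int, int]]:
    """(offset, mismatching pair count) for every window, one pair at a
    time against the complement of its mirror."""
    results = []
    for off in range(len(consensus) - core_len + 1):
        w = consensus[off : off + core_len]
        mm = 0
        for i in range(core_len // 2):
            left = set(IUPAC[w[i]])
            right_comp = {COMP[b] for b in IUPAC[w[core_len - 1 - i]]}
            if not (left & right_comp):
                mm += 1
        results.append((off, mm))
    return results


def gotoh_global(a: str, b: str, score, gap_open: float,
                 gap_extend: float) -> float:
    """Affine-gap global alignment score; a gap of length k costs
    gap_open + k * gap_extend.  Three-state dynamic program."""
    neg = float("-inf")
    n, m = len(a), len(b)
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + i * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + j * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = score(a[i - 1], b[j - 1])
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open + gap_extend,
                          X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open + gap_extend,
                          Y[i][j - 1] + gap_extend)
    return max(M[n][m], X[n][m], Y[n][m])


def tandem_arrays_naive(seq: str, min_period: int, max_period: int,
                        min_copies: int, max_divergence: float) -> list:
    """Maximal adjacency-chain tandem arrays plus greedy overlap
    resolution, computed with plain loops."""

    def ham(x: str, y: str) -> int:
        return sum(c != d for c, d in zip(x, y))

    n = len(seq)
    candidates = []
    for p in range(min_period, min(max_period, (n - 1) // 2) + 1):
        thr = math.floor(max_divergence * p)
        ok = [ham(seq[s : s + p], seq[s + p : s + 2 * p]) <= thr
              for s in range(n - 2 * p + 1)]
        for s in range(len(ok)):
            if not ok[s] or (s - p >= 0 and ok[s - p]):
                continue
            copies, k = 1, s
            while k < len(ok) and ok[k]:
                copies += 1
                k += p
            if copies >= min_copies:
                div = _naive_divergence(seq, s, p, copies)
                candidates.append((s, p, copies, div))
    candidates.sort(key=lambda c: (-c[2], c[3], c[0], c[1]))
    chosen = []
    for s, p, copies, div in candidates:
        span = (s, s + p * copies - 1)
        if all(span[1] < c[0] or span[0] > c[1] for c, *_ in chosen):
            chosen.append((span, p, copies))
    return sorted(chosen)


def _naive_divergence(seq: str, s: int, p: int, copies: int,
                      threshold: float = 0.25) -> float:
    cols = []
    rows = [seq[s + k * p : s + (k + 1) * p] for k in range(copies)]
    cons = []
    for j in range(p):
        col = [r[j] for r in rows]
        kept = {b for b in set(col) if col.count(b) / len(col) >= threshold}
        cons.append(kept or set(col))
    total = sum(
        sum(r[j] not in cons[j] for j in range(p)) for r in rows
    )
    return total / (copies * p)


def parity_blocks_naive(points: list[tuple[int, int, bool]],
                        min_block: int) -> list[tuple[str, int, int]]:
    """(kind, first index_a, last index_a) per block, scanning runs of
    unit steps in index_b left to right."""
    pts = sorted(points)
    blocks = []
    i = 0
    while i < len(pts):
        j = i + 1
        step = None
        while j < len(pts):
            d = pts[j][1] - pts[j - 1][1]
            if d in (1, -1) and (step is None or d == step):
                step = d
                j += 1
            else:
                break
        size = j - i
        if size < max(min_block, 2):
            kind = "dislocated"
        elif step == 1:
            kind = "collinear"
        else:
            kind = "inverted"
        blocks.append((kind, pts[i][0], pts[j - 1][0]))
        i = j
    return blocks
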