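"""IUPAC nucleotide ambiguity codes as base sets, plus matching helpers."""

from __future__ import annotations

CODE_TO_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "M": frozenset("AC"),
    "K": frozenset("GT"), "W": frozenset("AT"), "S": frozenset("CG"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

BASES_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in CODE_TO_BASES.items()}

_COMPLEMENT_BASE = {"A": "T", "C": "G", "G": "C", "T": "A"}


def code_for(bases: set[str] | frozenset[str]) -> str:
    """The minimal IUPAC code covering exactly ``bases``."""
    try:
        return BASES_TO_CODE[frozenset(bases)]
    except KeyError:
        raise ValueError(f"not a base set: {sorted(bases)}") from None


def complement_code(code: str) -> str:
    """IUPAC complement (e.g. D = A/G/T -> H = A/C/T)."""
    return code_for({_COMPLEMENT_BASE[b] for b in CODE_TO_BASES[code]})


def compatible(a: str, b: str) -> bool:
    """True when the base sets of two codes intersect."""
    return bool(CODE_TO_BASES[a] & CODE_TO_BASES[b])


def matches_at(text: str, motif: str, i: int) -> bool:
    """Exact-base text vs IUPAC motif at offset ``i`` (no bounds check)."""
    return all(text[i + j] in CODE_TO_BASES[m] for j, m in enumerate(motif))


def find_motif(text: str, motif: str) -> list[int]:
    """All 0-based offsets where the IUPAC ``motif`` matches ``text``."""
    m = len(motif)
    return [
        i for i in range(len(text) - m + 1) if matches_at(text, motif, i)
    ]
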