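"""Synthetic circular genomes with planted, fully known ground truth.

The generator emulates the architecture of an alphabaculovirus genome:
a circular ~100-140 kb dsDNA molecule with dense non-overlapping ORFs on
both strands, AT-biased intergenic background, 150 bp promoter windows
carrying planted TATA / DTAAG motifs (and scrubbed of chance motifs
otherwise), homologous-repeat arrays of ~66 bp elements with ~30 bp
imperfect palindrome cores, one non-palindromic ~29 bp repeat array, one
A/C-rich low-complexity run, and an optional CNE-like non-coding
element.  Every planted feature is recorded in a manifest so each
pipeline stage can be scored for exact recovery.

Idealizations (deliberate): promoter windows are resampled until their
motif content matches the intended class exactly, an in-frame stop codon
is placed immediately 5' of each planted start codon so the ORF caller's
longest-per-stop rule reproduces the planted interval exactly, and
repeat copies carry a fixed number of substitutions per copy rather
than an i.i.d. load, which bounds adjacent-copy divergence for any seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Feature, GenomeRecord, reverse_complement
from .promoters import PromoterConfig, classify_window

STOP = "TAA"
MIN_SPACER = 40
PROMOTER_CLASSES = ("early", "late", "both", "none")


@dataclass(frozen=True)
class OrfSpec:
    length_nt: int          # including start and stop codons; multiple of 3
    strand: str
    promoter_class: str = "none"

    def __post_init__(self) -> None:
        if self.length_nt < 9 or self.length_nt % 3:
            raise ValueError("ORF length must be a multiple of 3, >= 9")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if self.promoter_class not in PROMOTER_CLASSES:
            raise ValueError(f"unknown promoter class {self.promoter_class!r}")


@dataclass(frozen=True)
class RepeatSpec:
    klass: str              # hr | non_hr | ac_rich
    period: int
    n_full_copies: int
    n_truncated: int = 1
    mutations_per_copy: int = 2
    core_len: int = 30      # hr only
    core_mismatches: int = 2

    def __post_init__(self) -> None:
        if self.klass not in ("hr", "non_hr", "ac_rich"):
            raise ValueError(f"unknown repeat class {self.klass!r}")
        if self.klass == "hr" and self.core_len > self.period:
            raise ValueError("palindrome core longer than the element")


@dataclass
class SyntheticSpec:
    genome_len: int
    at_coding: float = 44.1       # percent AT in coding sequence
    at_intergenic: float = 59.8   # percent AT in spacers and windows
    orfs: list[OrfSpec] = field(default_factory=list)
    repeats: list[RepeatSpec] = field(default_factory=list)
    cne_like: int | None = None
    window_nt: int = 150
    seed: int = 0


@dataclass(frozen=True)
class PlantedOrf:
    start: int
    end: int
    strand: str
    length_nt: int
    promoter_class: str


@dataclass(frozen=True)
class PlantedRepeat:
    klass: str
    period: int
    template: str
    copies: tuple[tuple[int, int, bool], ...]
    core_offset: int | None = None
    core_mismatches: int | None = None

    @property
    def span(self) -> tuple[int, int]:
        return self.copies[0][0], self.copies[-1][1]

    @property
    def n_copies(self) -> int:
        return len(self.copies)


@dataclass
class SyntheticManifest:
    genome_len: int
    orfs: list[PlantedOrf]
    repeats: list[PlantedRepeat]
    cne: tuple[int, int] | None = None


# ---------------------------------------------------------------------------
# sampling helpers


def _base_probs(at_percent: float) -> np.ndarray:
    at = at_percent / 100.0
    return np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _sample_bases(rng: np.random.Generator, n: int, at_percent: float) -> str:
    idx = rng.choice(4, size=n, p=_base_probs(at_percent))
    return _BASES[idx].tobytes().decode()


def _sample_codons(rng: np.random.Generator, n_codons: int,
                   at_percent: float) -> str:
    """Stop-free codons with the requested AT bias (rejection sampling)."""
    out: list[str] = []
    while len(out) < n_codons:
        batch = _sample_bases(rng, 3 * (n_codons - len(out) + 8), at_percent)
        out.extend(
            c for i in range(0, len(batch) - 2, 3)
            if (c := batch[i : i + 3]) not in ("TAA", "TAG", "TGA")
        )
    return "".join(out[:n_codons])


def mutate_copies(template: str, n: int, rate: float,
                  seed: int | np.random.Generator,
                  alphabet: str = "ACGT") -> list[str]:
    """n copies of ``template`` with i.i.d. per-position substitutions to a
    uniformly chosen different base of ``alphabet``; rate in [0, 0.3]."""
    if not 0.0 <= rate <= 0.3:
        raise ValueError("mutation rate must be within [0, 0.3]")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    copies = []
    for _ in range(n):
        chars = list(template)
        hits = np.flatnonzero(rng.random(len(chars)) < rate)
        for i in hits:
            choices = [b for b in alphabet if b != chars[i]]
            chars[i] = choices[rng.integers(len(choices))]
        copies.append("".join(chars))
    return copies


def _mutate_exact(template: str, k: int, rng: np.random.Generator,
                  alphabet: str = "ACGT") -> str:
    """Exactly ``k`` substitutions at distinct positions (bounds the
    divergence between any two copies at 2k for every seed)."""
    chars = list(template)
    for i in rng.choice(len(chars), size=min(k, len(chars)), replace=False):
        choices = [b for b in alphabet if b != chars[i]]
        chars[i] = choices[rng.integers(len(choices))]
    return "".join(chars)


# ---------------------------------------------------------------------------
# cassette builders


def _build_window(rng: np.random.Generator, klass: str, window_nt: int,
                  at_percent: float) -> str:
    """A promoter window whose motif content is exactly the planted class.

    The window ends with an in-frame TAA (offsets 1-3) so the adjacent
    planted ATG starts its own ORF; motifs are planted upstream of it and
    the free background is resampled until no chance motif changes the
    classification.
    """
    config = PromoterConfig(window_nt=window_nt)
    free = window_nt - 3
    for _ in range(500):
        chars = list(_sample_bases(rng, free, at_percent))
        if klass in ("early", "both"):
            pos = int(rng.integers(0, free // 2 - 4))
            chars[pos : pos + 4] = "TATA"
        if klass in ("late", "both"):
            pos = int(rng.integers(free // 2, free - 5))
            d = "AGT"[rng.integers(3)]
            chars[pos : pos + 5] = d + "TAAG"
        window = "".join(chars) + STOP
        got, _hits = classify_window(window, config)
        if got == klass:
            return window
    raise RuntimeError(f"could not realize a {klass!r} promoter window")


def _build_orf_cassette(rng: np.random.Generator, orf: OrfSpec,
                        window_nt: int, at_coding: float,
                        at_intergenic: float) -> str:
    """window + ORF in coding orientation (reverse-complemented later for
    minus-strand placement)."""
    window = _build_window(rng, orf.promoter_class, window_nt, at_intergenic)
    body = _sample_codons(rng, orf.length_nt // 3 - 2, at_coding)
    return window + "ATG" + body + STOP


def _palindromic_template(rng: np.random.Generator, spec: RepeatSpec,
                          at_percent: float) -> tuple[str, int]:
    """An hr element embedding an imperfect palindrome core."""
    half = _sample_bases(rng, spec.core_len // 2, at_percent)
    core = list(half + reverse_complement(half))
    alphabet = "ACGT"
    for i in rng.choice(spec.core_len // 2, size=spec.core_mismatches,
                        replace=False):
        choices = [b for b in alphabet if b != core[i]]
        core[i] = choices[rng.integers(len(choices))]
    # center the core so small phase rotations of the detected element
    # keep it contiguous in the consensus
    offset = (spec.period - spec.core_len) // 2
    flank_l = _sample_bases(rng, offset, at_percent)
    flank_r = _sample_bases(rng, spec.period - spec.core_len - offset,
                            at_percent)
    return flank_l + "".join(core) + flank_r, offset


def _build_repeat(rng: np.random.Generator, spec: RepeatSpec,
                  at_percent: float) -> tuple[str, str, list[tuple[int, int, bool]], int | None]:
    """Returns (cassette, template, copy intervals local 1-based, core off)."""
    core_offset: int | None = None
    if spec.klass == "hr":
        template, core_offset = _palindromic_template(rng, spec, at_percent)
        copies = [_mutate_exact(template, spec.mutations_per_copy, rng)
                  for _ in range(spec.n_full_copies)]
    elif spec.klass == "non_hr":
        while True:
            template = _sample_bases(rng, spec.period, at_percent)
            if "G" in template and "T" in template:
                break
        copies = [_mutate_exact(template, min(spec.mutations_per_copy, 1), rng)
                  for _ in range(spec.n_full_copies)]
    else:  # ac_rich: alternate one flipped position; keeps neighbors 1 apart
        # reject templates with internal near-periodicity, which would let
        # a rotated/shorter period outscore the planted one
        while True:
            template = "".join("AC"[i] for i in rng.integers(0, 2, spec.period))
            rotations = (
                sum(a != b for a, b in zip(template, template[r:] + template[:r]))
                for r in range(1, spec.period)
            )
            if "A" in template and "C" in template and min(rotations) >= 4:
                break
        v = int(rng.integers(spec.period))
        variant = (template[:v]
                   + ("C" if template[v] == "A" else "A")
                   + template[v + 1 :])
        copies = [template if i % 2 == 0 else variant
                  for i in range(spec.n_full_copies)]
    intervals = []
    pos = 0
    for c in copies:
        intervals.append((pos + 1, pos + len(c), False))
        pos += len(c)
    parts = list(copies)
    for _ in range(spec.n_truncated):
        # ceil keeps the partial at the detectability floor (fraction 0.5)
        trunc = template[: (spec.period + 1) // 2]
        parts.append(trunc)
        intervals.append((pos + 1, pos + len(trunc), True))
        pos += len(trunc)
    return "".join(parts), template, intervals, core_offset


# ---------------------------------------------------------------------------
# genome assembly


def generate(spec: SyntheticSpec) -> tuple[GenomeRecord, SyntheticManifest]:
    """Emit a circular genome and its ground-truth manifest.

    Deterministic under ``spec.seed``; raises when the planted features
    cannot be placed without overlap.
    """
    rng = np.random.default_rng(spec.seed)

    cassettes: list[tuple[str, str, object]] = []  # (kind, seq, payload)
    for orf in spec.orfs:
        cas = _build_orf_cassette(rng, orf, spec.window_nt,
                                  spec.at_coding, spec.at_intergenic)
        if orf.strand == "-":
            cas = reverse_complement(cas)
        cassettes.append(("orf", cas, orf))
    for rep in spec.repeats:
        cas, template, intervals, core_off = _build_repeat(
            rng, rep, spec.at_intergenic)
        cassettes.append(("repeat", cas, (rep, template, intervals, core_off)))
    if spec.cne_like:
        cassettes.append(("cne", _sample_bases(rng, spec.cne_like,
                                               spec.at_intergenic), None))

    order = rng.permutation(len(cassettes))
    cassettes = [cassettes[i] for i in order]

    total_feat = sum(len(c[1]) for c in cassettes)
    n_gaps = len(cassettes) + 1
    leftover = spec.genome_len - total_feat - MIN_SPACER * n_gaps
    if leftover < 0:
        raise ValueError(
            f"features need {total_feat + MIN_SPACER * n_gaps} bp but the "
            f"genome is only {spec.genome_len} bp"
        )
    extra = rng.multinomial(leftover, np.full(n_gaps, 1.0 / n_gaps))
    spacer_lens = [MIN_SPACER + int(e) for e in extra]

    parts: list[str] = []
    pos = 0  # 0-based length so far
    orfs_out: list[PlantedOrf] = []
    repeats_out: list[PlantedRepeat] = []
    cne_out: tuple[int, int] | None = None
    features: list[Feature] = []

    def emit(seq: str) -> int:
        nonlocal pos
        parts.append(seq)
        start = pos + 1
        pos += len(seq)
        return start

    for gap_len, (kind, cas, payload) in zip(spacer_lens, cassettes):
        emit(_sample_bases(rng, gap_len, spec.at_intergenic))
        start = emit(cas)
        if kind == "orf":
            orf: OrfSpec = payload
            if orf.strand == "+":
                o_start = start + spec.window_nt
                o_end = start + len(cas) - 1
            else:
                o_start = start
                o_end = start + orf.length_nt - 1
            orfs_out.append(PlantedOrf(o_start, o_end, orf.strand,
                                       orf.length_nt, orf.promoter_class))
            features.append(Feature("CDS", [(o_start, o_end)], orf.strand,
                                    {"gene": f"orf{len(orfs_out):03d}"}))
        elif kind == "repeat":
            rep, template, intervals, core_off = payload
            copies = tuple((a + start - 1, b + start - 1, t)
                           for a, b, t in intervals)
            repeats_out.append(PlantedRepeat(
                rep.klass, rep.period, template, copies,
                core_offset=core_off,
                core_mismatches=rep.core_mismatches if rep.klass == "hr" else None,
            ))
            features.append(Feature("repeat_region",
                                    [(copies[0][0], copies[-1][1])], "+",
                                    {"note": rep.klass}))
        else:
            cne_out = (start, start + len(cas) - 1)
            features.append(Feature("misc_feature", [cne_out], "+",
                                    {"note": "cne_like"}))
    emit(_sample_bases(rng, spacer_lens[-1], spec.at_intergenic))

    sequence = "".join(parts)
    assert len(sequence) == spec.genome_len
    record = GenomeRecord("synthetic", sequence, circular=True,
                          features=features)
    manifest = SyntheticManifest(spec.genome_len, orfs_out, repeats_out,
                                 cne_out)
    return record, manifest


def parse_spec_file(path, seed: int) -> SyntheticSpec:
    """Parse a plain key-value spec file.

    Scalar lines are ``key = value``; repeated lines describe features::

        genome_len = 100000
        at_coding = 44.1
        orf = 300 + early
        repeat = hr 66 13
        cne_like = 156
    """
    from pathlib import Path

    scalars: dict[str, str] = {}
    orfs: list[OrfSpec] = []
    repeats: list[RepeatSpec] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed spec line: {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key == "orf":
            length, strand, *klass = value.split()
            orfs.append(OrfSpec(int(length), strand,
                                klass[0] if klass else "none"))
        elif key == "repeat":
            klass, period, copies, *rest = value.split()
            repeats.append(RepeatSpec(klass, int(period), int(copies),
                                      int(rest[0]) if rest else 1))
        elif key in ("genome_len", "cne_like", "window_nt"):
            scalars[key] = value
        elif key in ("at_coding", "at_intergenic"):
            scalars[key] = value
        else:
            raise ValueError(f"unknown spec key {key!r}")
    if "genome_len" not in scalars:
        raise ValueError("spec file must set genome_len")
    return SyntheticSpec(
        genome_len=int(scalars["genome_len"]),
        at_coding=float(scalars.get("at_coding", 44.1)),
        at_intergenic=float(scalars.get("at_intergenic", 59.8)),
        orfs=orfs,
        repeats=repeats,
        cne_like=int(scalars["cne_like"]) if "cne_like" in scalars else None,
        window_nt=int(scalars.get("window_nt", 150)),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# the reference study-scale specification


def dapu_scale_spec(seed: int = 0, n_orfs: int = 100,
                    genome_len: int = 136_761) -> SyntheticSpec:
    """A genome-scale specification mirroring the reference architecture:
    ~137 kb circular genome, dense two-strand ORFs, five hr regions of
    66 bp elements with copy counts 13/6/10/5/4, one 29 bp non-hr array
    of 16 copies and one 12 bp A/C-rich run, each array ending in one
    truncated element."""
    lengths = [300, 450, 600, 750, 900, 1050, 1200, 1500, 1800, 2400]
    # ~47:53 forward:reverse, interleaved like a real two-strand gene map
    strand_cycle = "+-+--+-+--"
    orfs = [
        OrfSpec(
            lengths[i % len(lengths)],
            strand_cycle[i % len(strand_cycle)],
            PROMOTER_CLASSES[i % 4],
        )
        for i in range(n_orfs)
    ]
    # copy totals follow the truncated-counts-as-one convention: each array
    # carries one truncated terminal element inside its printed total
    repeats = [
        RepeatSpec("hr", 66, 12),
        RepeatSpec("hr", 66, 5),
        RepeatSpec("hr", 66, 9),
        RepeatSpec("hr", 66, 4),
        RepeatSpec("hr", 66, 3),
        RepeatSpec("non_hr", 29, 15),
        RepeatSpec("ac_rich", 12, 15),
    ]
    return SyntheticSpec(genome_len=genome_len, orfs=orfs, repeats=repeats,
                         cne_like=156, seed=seed)
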