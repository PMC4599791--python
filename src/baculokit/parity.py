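"""Homolog mapping, gene-parity tables and gene-order rearrangements.

Homology between two annotated genomes is operationalized as reciprocal
best hits (RBH) of global protein alignments (BLOSUM62, affine gaps).
Parity points pair the polh-first serial indices of homologous ORFs;
runs of points with unit index steps form collinear (+1) or inverted
(-1) blocks, and points breaking both patterns are dislocations.

Gap scoring convention: a gap of length k costs ``gap_open +
k * gap_extend`` (both negative), the NCBI-style affine form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .orfs import OrfTable

log = logging.getLogger(__name__)

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")
DEFAULT_GAP_OPEN = -11
DEFAULT_GAP_EXTEND = -1
DEFAULT_MIN_SCORE = 50


@dataclass(frozen=True)
class ProteinAlignment:
    score: float
    identity_pct: float
    positivity_pct: float
    aligned_columns: int


@dataclass
class HomologTable:
    """Reciprocal-best-hit pairs between two proteomes."""

    pairs: list[tuple[str, str, float, float]]  # (id_A, id_B, score, identity)

    @property
    def shared_count(self) -> int:
        return len(self.pairs)


@dataclass
class ParityTable:
    points: list[tuple[int, int, bool]]  # (index_A, index_B, strand_concordant)


@dataclass(frozen=True)
class CollinearBlock:
    span_a: tuple[int, int]
    span_b: tuple[int, int]
    kind: str  # collinear | inverted | dislocated
    n_points: int


def _check_protein(seq: str, label: str) -> str:
    seq = seq.upper()
    for i, c in enumerate(seq, start=1):
        if c not in PROTEIN_ALPHABET:
            raise ValueError(f"{label}: illegal residue {c!r} at position {i}")
    return seq


def _make_aligner(matrix_name: str, gap_open: float, gap_extend: float,
                  mode: str = "global") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # Biopython charges open on the first gap position; fold the extend in
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    return aligner


def _column_stats(row_a: str, row_b: str, matrix) -> tuple[float, float, int]:
    """Identity/positivity over aligned columns, terminal gaps excluded."""
    first = max(len(row_a) - len(row_a.lstrip("-")),
                len(row_b) - len(row_b.lstrip("-")))
    last = min(len(row_a.rstrip("-")), len(row_b.rstrip("-")))
    ident = positive = cols = 0
    for a, b in zip(row_a[first:last], row_b[first:last]):
        cols += 1
        if a == "-" or b == "-":
            continue
        if a == b:
            ident += 1
        if matrix is not None and matrix[a, b] > 0:
            positive += 1
    if cols == 0:
        return 0.0, 0.0, 0
    return 100.0 * ident / cols, 100.0 * positive / cols, cols


def global_align(protein_a: str, protein_b: str,
                 matrix: str = "BLOSUM62",
                 gap_open: float = DEFAULT_GAP_OPEN,
                 gap_extend: float = DEFAULT_GAP_EXTEND) -> ProteinAlignment:
    """Optimal global protein alignment score with identity/positivity."""
    a = _check_protein(protein_a, "protein_a")
    b = _check_protein(protein_b, "protein_b")
    if not a or not b:
        raise ValueError("empty protein sequence")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    ident, positive, cols = _column_stats(row_a, row_b,
                                          aligner.substitution_matrix)
    return ProteinAlignment(float(aln.score), ident, positive, cols)


def nucleotide_identity(seq_a: str, seq_b: str, match: float = 2.0,
                        mismatch: float = -3.0, gap_open: float = -5.0,
                        gap_extend: float = -2.0) -> float:
    """Global nucleotide alignment identity over aligned columns (%)."""
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    ident, _, _ = _column_stats(str(aln[0]), str(aln[1]), None)
    return ident


def reciprocal_best_hits(proteome_a: dict[str, str], proteome_b: dict[str, str],
                         min_score: float = DEFAULT_MIN_SCORE,
                         matrix: str = "BLOSUM62",
                         gap_open: float = DEFAULT_GAP_OPEN,
                         gap_extend: float = DEFAULT_GAP_EXTEND) -> HomologTable:
    """RBH homolog pairing between two proteomes (id -> sequence maps).

    A pair (a, b) is kept iff b is a's unique best score, a is b's unique
    best score, and the score reaches ``min_score``; ties leave the ORF
    unpaired with a logged warning.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("empty proteome")
    ids_a, ids_b = list(proteome_a), list(proteome_b)
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    scores: dict[tuple[str, str], float] = {}
    alignments: dict[tuple[str, str], tuple[str, str]] = {}
    for ia in ids_a:
        sa = _check_protein(proteome_a[ia], ia)
        for ib in ids_b:
            aln = aligner.align(sa, _check_protein(proteome_b[ib], ib))[0]
            scores[ia, ib] = float(aln.score)
            alignments[ia, ib] = (str(aln[0]), str(aln[1]))

    def unique_best(keys: list[float]) -> bool:
        top = max(keys)
        return keys.count(top) == 1

    best_a = {}
    for ia in ids_a:
        row = [scores[ia, ib] for ib in ids_b]
        if not unique_best(row):
            log.warning("tied best hits for %s; left unpaired", ia)
            continue
        best_a[ia] = ids_b[row.index(max(row))]
    best_b = {}
    for ib in ids_b:
        col = [scores[ia, ib] for ia in ids_a]
        if not unique_best(col):
            log.warning("tied best hits for %s; left unpaired", ib)
            continue
        best_b[ib] = ids_a[col.index(max(col))]

    pairs = []
    matrix_obj = aligner.substitution_matrix
    for ia, ib in best_a.items():
        if best_b.get(ib) == ia and scores[ia, ib] >= min_score:
            ident, _, _ = _column_stats(*alignments[ia, ib], matrix_obj)
            pairs.append((ia, ib, scores[ia, ib], ident))
    return HomologTable(pairs=sorted(pairs))


def gene_parity(table_a: OrfTable, table_b: OrfTable,
                homologs: HomologTable) -> ParityTable:
    """Parity points of homolog pairs in polh-first serial indices."""
    by_name_a = {o.name: (i, o.strand)
                 for i, o in enumerate(table_a.orfs, start=1) if o.name}
    by_name_b = {o.name: (i, o.strand)
                 for i, o in enumerate(table_b.orfs, start=1) if o.name}
    points = []
    for id_a, id_b, _score, _ident in homologs.pairs:
        if id_a not in by_name_a:
            raise ValueError(f"homolog references unknown ORF {id_a!r} in genome A")
        if id_b not in by_name_b:
            raise ValueError(f"homolog references unknown ORF {id_b!r} in genome B")
        ia, sa = by_name_a[id_a]
        ib, sb = by_name_b[id_b]
        points.append((ia, ib, sa == sb))
    points.sort()
    return ParityTable(points=points)


def detect_rearrangements(parity: ParityTable,
                          min_block: int = 2) -> list[CollinearBlock]:
    """Decompose parity points into collinear / inverted / dislocated blocks.

    Maximal runs of successive points (in genome-A order) whose
    genome-B indices step +1 are collinear and -1 inverted; runs shorter
    than ``min_block`` and points breaking both patterns are dislocated.
    """
    points = sorted(parity.points)
    if not points:
        raise ValueError("empty parity table")
    runs: list[list[tuple[int, int, bool]]] = []
    run = [points[0]]
    direction = 0
    for prev, cur in zip(points, points[1:]):
        step = cur[1] - prev[1]
        if step in (1, -1) and (direction in (0, step)):
            run.append(cur)
            direction = step
        else:
            runs.append(run)
            run, direction = [cur], 0
    runs.append(run)
    blocks = []
    for run in runs:
        ia = (run[0][0], run[-1][0])
        bs = [p[1] for p in run]
        ib = (min(bs), max(bs))
        if len(run) < max(min_block, 2):
            kind = "dislocated"
        elif bs[-1] >= bs[0]:
            kind = "collinear"
        else:
            kind = "inverted"
        blocks.append(CollinearBlock(ia, ib, kind, len(run)))
    return blocks


def plot_parity(parity: ParityTable, path, label_a: str = "genome A",
                label_b: str = "genome B") -> None:
    """Scatter plot of the gene-parity table."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = [p[0] for p in parity.points]
    ys = [p[1] for p in parity.points]
    colors = ["tab:blue" if p[2] else "tab:red" for p in parity.points]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(xs, ys, s=12, c=colors)
    ax.set_xlabel(f"ORF index in {label_a} (polh = 1)")
    ax.set_ylabel(f"ORF index in {label_b} (polh = 1)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
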