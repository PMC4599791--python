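"""Concatenated-gene supermatrix, p-distances, NJ and bootstrap support.

This is a deliberate desk-scale, distance-based stand-in for full
maximum-likelihood phylogenomics: per-gene alignments are concatenated
into one supermatrix with a partition map, pairwise p-distances are
computed with pairwise gap deletion, a neighbor-joining tree is inferred
and column-bootstrap support attached to the internal bipartitions of
the point-estimate tree.  It makes no claim to reproduce model-based
(LG+G+I+F) inference or divergence-time estimates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from io import StringIO

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

log = logging.getLogger(__name__)

GAP = "-"


@dataclass
class Supermatrix:
    taxa: list[str]
    rows: dict[str, str]
    partitions: list[tuple[str, int, int]]  # (gene, start, end) 1-based columns

    @property
    def columns(self) -> int:
        return len(next(iter(self.rows.values())))


@dataclass
class PhyloTree:
    """An unrooted tree with optional bootstrap support per bipartition."""

    tree: TreeNode
    taxa: list[str]
    support: dict[frozenset[str], float] = field(default_factory=dict)

    def bipartitions(self) -> set[frozenset[str]]:
        return tree_bipartitions(self.tree, self.taxa)

    def to_newick(self) -> str:
        t = self.tree.copy()
        if self.support:
            all_taxa = set(self.taxa)
            for node in t.non_tips():
                side = frozenset(leaf.name for leaf in node.tips())
                key = _canonical_split(side, all_taxa, self.taxa[0])
                if key in self.support:
                    node.name = f"{self.support[key]:g}"
        out = StringIO()
        t.write(out, format="newick")
        return out.getvalue().strip()


def concatenate(per_gene_alignments: list[tuple[str, dict[str, str]]]
                ) -> Supermatrix:
    """Concatenate named per-gene alignments sharing one taxon set."""
    if not per_gene_alignments:
        raise ValueError("no alignments given")
    taxa = sorted(per_gene_alignments[0][1])
    rows = {t: [] for t in taxa}
    partitions = []
    pos = 1
    for name, aln in per_gene_alignments:
        if sorted(aln) != taxa:
            missing = set(taxa) ^ set(aln)
            raise ValueError(
                f"alignment {name!r}: taxon set mismatch, difference {sorted(missing)}"
            )
        lengths = {len(s) for s in aln.values()}
        if len(lengths) != 1:
            raise ValueError(f"alignment {name!r}: rows of unequal length")
        width = lengths.pop()
        for t in taxa:
            rows[t].append(aln[t].upper())
        partitions.append((name, pos, pos + width - 1))
        pos += width
    return Supermatrix(taxa, {t: "".join(p) for t, p in rows.items()}, partitions)


def p_distance(matrix: Supermatrix) -> np.ndarray:
    """Pairwise fraction of differing sites, pairwise gap deletion."""
    taxa = matrix.taxa
    if len(taxa) < 2:
        raise ValueError("need at least two taxa")
    arrs = {t: np.frombuffer(matrix.rows[t].encode(), dtype=np.uint8)
            for t in taxa}
    gap = ord(GAP)
    k = len(taxa)
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrs[taxa[i]], arrs[taxa[j]]
            usable = (a != gap) & (b != gap)
            n = int(usable.sum())
            if n == 0:
                raise ValueError(
                    f"no comparable columns between {taxa[i]} and {taxa[j]}"
                )
            d = float((a[usable] != b[usable]).sum()) / n
            dist[i, j] = dist[j, i] = d
    return dist


def neighbor_joining(dist: np.ndarray, taxa: list[str]) -> PhyloTree:
    """Standard NJ agglomeration; negative branch lengths clamped to 0."""
    dist = np.asarray(dist, dtype=float)
    if dist.shape != (len(taxa), len(taxa)):
        raise ValueError("distance matrix does not match the taxon list")
    if len(taxa) < 3:
        raise ValueError("need at least three taxa")
    if np.max(np.abs(dist - dist.T)) > 1e-9:
        raise ValueError("distance matrix is asymmetric beyond 1e-9")
    dist = (dist + dist.T) / 2.0
    tree = nj(DistanceMatrix(dist, ids=taxa))
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        log.warning("clamped %d negative branch lengths to 0", clamped)
    return PhyloTree(tree, list(taxa))


def _canonical_split(side: frozenset[str], all_taxa: set[str],
                     anchor: str) -> frozenset[str]:
    """Represent each bipartition by the side not containing the anchor."""
    return frozenset(all_taxa - side) if anchor in side else side


def tree_bipartitions(tree: TreeNode, taxa: list[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions (internal edges) of an unrooted tree."""
    all_taxa = set(taxa)
    anchor = taxa[0]
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(leaf.name for leaf in node.tips())
        if 2 <= len(side) <= len(all_taxa) - 2:
            splits.add(_canonical_split(side, all_taxa, anchor))
    return splits


def _resample(matrix: Supermatrix, rng: np.random.Generator) -> Supermatrix:
    cols = rng.integers(0, matrix.columns, size=matrix.columns)
    rows = {}
    for t in matrix.taxa:
        row = matrix.rows[t]
        rows[t] = "".join(row[c] for c in cols)
    return Supermatrix(matrix.taxa, rows,
                       [("bootstrap", 1, matrix.columns)])


def bootstrap_support(matrix: Supermatrix, n_replicates: int,
                      seed: int) -> PhyloTree:
    """NJ tree with column-bootstrap support on its internal edges.

    Columns are resampled with replacement (partition-blind); support is
    the percentage of replicates whose NJ tree contains each internal
    bipartition of the point-estimate tree.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    point = neighbor_joining(p_distance(matrix), matrix.taxa)
    target = point.bipartitions()
    counts = {split: 0 for split in target}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        rep = _resample(matrix, rng)
        rep_tree = neighbor_joining(p_distance(rep), rep.taxa)
        found = rep_tree.bipartitions()
        for split in target:
            if split in found:
                counts[split] += 1
    point.support = {
        s: 100.0 * c / n_replicates for s, c in counts.items()
    }
    return point


# ---------------------------------------------------------------------------
# sequence simulation down a known tree (for parameter-recovery checks)

#: a clade is ("name", branch_length) for a leaf or ((child, ...), length)
Clade = tuple


def simulate_alignment(tree: Clade, n_sites: int, seed: int) -> dict[str, str]:
    """Simulate nucleotide sequences down a tree under the Jukes-Cantor
    model (branch lengths in expected substitutions per site).

    ``tree`` is a nested ``(payload, length)`` pair where payload is a
    leaf name or a tuple of child clades; pass length 0.0 at the root.
    """
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    root = rng.integers(0, 4, size=n_sites)
    out: dict[str, str] = {}

    def evolve(state: np.ndarray, length: float) -> np.ndarray:
        p = 0.75 * (1.0 - math.exp(-4.0 * length / 3.0))
        hit = rng.random(n_sites) < p
        new = state.copy()
        if hit.any():
            shift = rng.integers(1, 4, size=int(hit.sum()))
            new[hit] = (new[hit] + shift) % 4
        return new

    def walk(node: Clade, state: np.ndarray) -> None:
        payload, length = node
        state = evolve(state, length)
        if isinstance(payload, str):
            out[payload] = bases[state].tobytes().decode()
        else:
            for child in payload:
                walk(child, state)

    walk(tree, root)
    return out


#: reference six-taxon tree for parameter-recovery experiments: three
#: cherries separated by internal edges of 0.05-0.1 substitutions/site
REFERENCE_TREE6: Clade = (
    (
        (
            (
                (((("A", 0.05), ("B", 0.05)), 0.1)),
                (((("C", 0.05), ("D", 0.05)), 0.1)),
            ),
            0.05,
        ),
        ((("E", 0.05), ("F", 0.15)), 0.05),
    ),
    0.0,
)


def topology_recovery_rate(n_replicates: int, n_sites: int, seed: int,
                           tree: Clade = REFERENCE_TREE6) -> float:
    """Fraction of replicates in which NJ on p-distances recovers the
    generating topology (all true bipartitions present)."""
    leaves: list[str] = []

    def collect(node: Clade) -> TreeNode:
        payload, length = node
        if isinstance(payload, str):
            leaves.append(payload)
            return TreeNode(name=payload, length=length)
        children = [collect(c) for c in payload]
        return TreeNode(length=length, children=children)

    true_tree = collect(tree)
    truth = tree_bipartitions(true_tree, sorted(leaves))
    hits = 0
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(2**31 - 1))
        aln = simulate_alignment(tree, n_sites, rep_seed)
        sm = concatenate([("sim", aln)])
        est = neighbor_joining(p_distance(sm), sm.taxa)
        if tree_bipartitions(est.tree, sorted(leaves)) == truth:
            hits += 1
    return hits / n_replicates
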