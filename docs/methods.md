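# Methods

This note documents the models and procedures behind baculokit, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Coordinate model

All coordinates are 1-based and inclusive (GenBank convention), in every
module and in the GFF3 output. A feature spanning the origin of a
circular genome is exactly two intervals, `(x, L)` then `(1, y)`. With
this convention the conserved non-coding element at 6,994–7,149 has
length 7,149 − 6,994 + 1 = 156 bp, and all per-feature statistics are
invariant under rotation of a circular genome.

## ORF calling

The caller scans all six frames. Circular sequences are scanned doubled
so every stop codon is seen once with its full upstream context; ORFs
are keyed by their stop codon and, per stop, only the 5'-most ATG after
the previous in-frame stop is reported (equivalently, the longest ORF
per stop). Defaults: start codon ATG only, stops TAA/TAG/TGA (standard
code), minimum length 150 nt including the stop (50 codons — a common
annotation floor for baculovirus genomes; the choice is exposed).
Overlapping ORFs on either strand are all reported, because baculovirus
genes overlap freely; no overlap filtering is applied. An important
scope note: published baculovirus annotations are typically the
consensus of several gene finders plus homology evidence, so this single
deterministic caller is *not* expected to reproduce a deposited ORF
catalogue from raw sequence; accession-level ORF counts are therefore
evaluated on the deposited CDS features, not on de novo calls.

*polh*-first renumbering reverse-complements the genome if *polh* lies
on the minus strand, rotates so *polh* starts at position 1, and assigns
serial ids clockwise. The forward:reverse census is taken after this
normalization, matching how orientation ratios are reported in genome
papers.

Single-substitution effects translate the affected codon before and
after the change; codon index is ⌈position/3⌉ from the first base of the
start codon.

## Promoter classification

Early/late promoter classes are motif presence calls in the 150 bp
window immediately 5' of the start codon, read on the ORF's coding
strand (wrapping the origin on circular genomes; truncated and flagged
on linear ones). TATA is matched literally; the late box DTAAG uses
IUPAC D = A/G/T. No positional constraint is imposed inside the window,
and windows are not truncated when they overlap a neighboring CDS. Both
motifs are configuration-overridable. Only the coding strand is
searched: the late TAAG motif is a transcription-start signal read on
the sense strand.

## Composition

AT% excludes N from numerator and denominator; percentages *of the
genome* use the N-inclusive length. Reported values are rounded half-up
to one decimal; internal computations keep full precision, and the
whole-genome AT equals the coverage-weighted mean of CDS-union AT and
intergenic AT to 1e-9. Intergenic is the complement of the union of all
CDS features regardless of strand (overlaps count once); repeat features
are not subtracted.

## Repeat discovery and classification

**Detector.** An array of period *p* is a maximal chain of consecutive
*p*-blocks in which every adjacent pair differs at ≤ ⌊d·p⌋ positions
(default divergence d = 0.15). The scan is exhaustive — every period in
[10, 80] and every phase, vectorized with cumulative-sum block Hamming
distances — not seeded, so detection has no sensitivity parameter beyond
the rule itself. Overlapping candidates (phases, harmonics) are resolved
by more copies, then lower mean divergence, then smaller start. When a
truncated-element fraction is configured, a valid truncated terminal
copy counts toward a candidate's total during resolution; this makes the
in-phase reading of an array that ends in a partial element outrank its
rotated alternatives, which otherwise tie on full copies.

**Consensus.** The strict consensus takes, per column, the minimal IUPAC
code covering every base whose frequency among non-gap symbols reaches
the ambiguity threshold (default 0.25); when nothing reaches it, the
code covers all observed bases. Inputs may themselves carry IUPAC codes
(a code contributes to every base it covers), which makes the operation
idempotent. N is treated as uninformative, like a gap.

**Palindrome core.** A window of even length (default 30) slides along
the consensus; a mirror pair (i, w−1−i) mismatches when the base set at
i does not intersect the complement of the set at its mirror. The
lowest-mismatch window (leftmost on ties) is reported if ≤ 4 mismatches.
A poly-A window scores 15/15 pairs incompatible — palindromy is a
property of complementarity, not symmetry.

**Classification.** A/C-rich if the consensus alphabet ⊆ {A, C, M};
else *hr* if a qualifying palindrome core exists (an element shorter
than the core window cannot qualify); else non-*hr*.

**Copy counting.** Greedy left-to-right scan for consensus-compatible
windows with ≤ ⌈0.15·p⌉ incompatible positions, advancing one period on
a match. A terminal partial covering ≥ half the consensus (pro-rata
mismatch budget, longest valid length) counts as one copy — the
convention used when repeat tables state that every truncated element
was counted as one. Copy totals in this package follow that convention:
a printed total of 13 means 12 full copies plus one truncated element.

Detected region boundaries are a property of the detector's phase
choice; when copies carry substitutions, several rotations of the same
array are equally valid readings, so recovery guarantees cover class,
period and copy count exactly, and location up to a sub-period shift.

## Homology and gene parity

Homology is operationalized as reciprocal best hits under global
(Needleman–Wunsch-style) protein alignment with BLOSUM62 and affine gaps
costing `gap_open + k·gap_extend` for a gap of length k (defaults
−11/−1, minimum score 50). Ties for best hit leave the ORF unpaired with
a warning — an ambiguous homolog is worse than a missing one for
order-based analysis. Identity and positivity percentages are computed
over aligned columns excluding terminal gaps; internal gap columns count
in the denominator. Published homolog totals between related genomes
depend on unstated search settings, so RBH counts are treated as a sanity
band rather than an exact target. Genome-scale nucleotide identity is
likewise out of scope for exact reproduction (it depends on whole-genome
aligner configuration); the nucleotide aligner is intended for
interval-scale comparisons such as the CNE.

Rearrangement calls are gene-order-level: runs of parity points with
index_B steps of +1 are collinear, −1 inverted, and runs shorter than
`min_block` (default 2) or points breaking both patterns are
dislocations. Points join the earliest compatible run when two runs
could share a boundary point.

## Phylogeny stand-in

The phylogeny module is deliberately a distance method: p-distances with
pairwise gap deletion, neighbor joining (negative branch lengths clamped
to zero with a warning), and column bootstrap (partition-blind, matching
standard practice; per-partition resampling exists but defaults off).
It documents itself as a stand-in and makes no claim to reproduce
model-based ML topologies or divergence-time estimates. Its acceptance
property is parameter recovery: on sequences simulated down a known
6-taxon tree under Jukes–Cantor (leaf branches 0.05–0.15, internal
branches 0.05–0.1 substitutions/site, 400 sites), NJ must recover the
true topology in ≥ 95 of 100 replicates; observed recovery is 100/100
across seeds.

## Synthetic genomes

The generator emulates the architecture of an alphabaculovirus genome:
circular, ~100–140 kb, dense non-overlapping ORF cassettes on both
strands, AT-biased background (defaults: coding 44.1% AT, intergenic
59.8% AT, chosen so a genome ~90% coding blends to ~45.6%), five 66 bp
*hr* arrays with centered 30 bp imperfect palindrome cores (2 planted
mismatches), one 29 bp non-*hr* array, one 12 bp A/C-rich run, and an
optional 156 bp CNE-like element. The study-scale specification
(`dapu_scale_spec`) is 136,761 bp with 100 ORFs (lengths cycling
300–2,400 nt, ≈47:53 forward:reverse) and repeat copy totals
13/6/10/5/4, 16 and 16, each including one truncated terminal element.

Deliberate idealizations, and what they imply:

* Promoter windows are resampled until their motif content matches the
  intended class exactly, so promoter recovery is exact rather than
  statistical. Real windows contain incidental motifs; passing tests
  demonstrate correctness of the classifier, not its specificity on
  real genomes.
* An in-frame stop codon is placed immediately 5' of each planted ATG,
  so the caller's longest-per-stop rule reproduces planted intervals
  exactly. Real genes may have upstream in-frame ATGs; on real data the
  caller reports the longest open frame, as annotation pipelines do
  before homology curation.
* Planted coding sequence is sampled codon-wise with rejection of stop
  codons and the target AT bias — no codon-usage table is imposed.
* Repeat copies carry a fixed number of substitutions per copy (default
  2 for *hr*, 1 for non-*hr*, and an alternating single-position A/C
  flip for the low-complexity run). A fixed count bounds adjacent-copy
  divergence for every seed, making recovery deterministic, whereas an
  i.i.d. load (available as `mutate_copies`, the general-purpose
  operation) occasionally exceeds the adjacency threshold and splits an
  array. The A/C-rich template is rejected if any rotation of it lies
  within 3 mismatches of itself, which would let a rotated or shorter
  period outscore the planted one.
* Chance features do occur in the background (short spurious ORFs, and
  in principle spurious arrays, though none were observed in 10 × 10 kb
  random replicates); recovery is therefore asserted as
  planted ⊆ detected, with exact attributes on the planted set.

Same specification + seed gives byte-identical genome and manifest; the
whole-genome AT of the emitted sequence stays within ±1.5 points of the
length-weighted blend of the coding/intergenic targets.

## Problem sizes

The default verification workloads are sized for a desk run: the
study-scale recovery genome is 136,761 bp (one generation ≈ 0.1 s,
repeat discovery ≈ 0.3 s), oracle-equivalence suites use 50 random
instances per operation (300 bp genomes, 8-residue proteins, 15-point
permutations, 40 nt consensus strings), and the phylogeny experiment
uses 100 replicates of 400 sites.

## Known limitations

* The ORF caller is a single deterministic annotator; it does not fold
  in homology evidence and will not match curated ORF catalogues
  number-for-number from raw sequence.
* Repeat-region boundaries are phase-resolved heuristically; only class,
  period and copy count are guaranteed exactly on planted data.
* The RBH criterion with fixed gap costs is one operationalization of
  homology; counts shift with scoring parameters.
* The NJ tree is a stand-in; no substitution-model fitting, rate
  heterogeneity or dating is provided.
* GenBank writing is not supported (reading only); GFF3 is the output
  annotation format.
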