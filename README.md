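# baculokit

A characterization toolkit for circular baculovirus genomes, built for the
kind of comparative-genomics study that follows the sequencing of a new
nucleopolyhedrovirus (NPV): call ORFs on the circular genome, renumber them
with *polh* (polyhedrin) as ORF 1 in clockwise orientation, classify
promoters from upstream motifs, compute composition statistics, discover
and classify repeated regions — homologous regions (*hrs*) with imperfect
palindrome cores, non-*hr* arrays and A/C-rich runs — compare gene order
against a related genome, and infer a light distance-based phylogeny.
Every stage can be exercised end-to-end on synthetic genomes with planted
ground truth, so the whole pipeline is testable without downloads.

## What it computes

* **ORF calling** — all six reading frames of a circular genome are
  scanned, frames continuing across the origin; for each stop codon only
  the longest upstream ATG-initiated ORF is reported (default minimum 150
  nt, i.e. 50 codons). ORFs are renumbered *polh*-first: the origin is
  conceptually rotated so *polh* starts at position 1 on the plus strand,
  and the forward:reverse orientation census is reported.
* **Promoter classes** — the 150 bp window 5' of each start codon, on the
  ORF's coding strand, is scanned for a TATA box (early promoter) and a
  DTAAG box (late; IUPAC D = A/G/T). Both motifs → *both*; neither →
  *none*.
* **Composition** — AT% is `100·(A+T)/(A+C+G+T)` with N excluded;
  intergenic regions are the strand-blind complement of the CDS union,
  wrap-aware, reported as bp, % of genome and AT%.
* **Repeats** — a tandem array of period *p* is a maximal chain of
  adjacent *p*-blocks differing at ≤ ⌊0.15·*p*⌋ positions, found
  exhaustively over periods 10–80. Each array gets a strict IUPAC
  consensus (per column, the minimal code covering every base at ≥ 25%
  frequency). An array is an *hr* when its consensus contains a 30 bp
  imperfect palindrome with ≤ 4 incompatible mirror pairs, A/C-rich when
  the consensus alphabet is within {A, C, M}, otherwise non-*hr*. Copy
  counting is a greedy left-to-right consensus scan in which a truncated
  terminal element (≥ half an element) counts as one copy.
* **Gene parity** — homologs between two annotated genomes are reciprocal
  best hits of global protein alignments (BLOSUM62, affine gaps −11/−1);
  parity points pair *polh*-first serial indices, and runs with index_B
  steps of +1 / −1 become collinear / inverted blocks, with isolated
  points called dislocations.
* **Phylogeny (stand-in)** — per-gene alignments are concatenated into a
  partitioned supermatrix; pairwise p-distances (pairwise gap deletion)
  feed neighbor joining, with column-bootstrap support. This deliberately
  replaces model-based maximum-likelihood inference at desk scale.

## Worked example

Simulate a 20 kb genome with four ORFs (one promoter class each), three
repeat regions and a 156 bp non-coding element, then run the callers:

```sh
baculokit simulate --spec spec.cfg --seed 42 --out run
baculokit annotate run/genome.fasta --out run
baculokit repeats run/genome.fasta --out run
baculokit composition run/genome.fasta --interval 6994:7149 --out run
```

`run/repeats.tsv` (first seven columns):

```
name      class    start  end    period  copies  truncated
A-C rich  ac_rich  6815   6918   12      9       1
non-hr    non_hr   15689  15881  29      7       1
hr1       hr       17731  18100  66      6       1
```

The planted truth (`run/truth.tsv`) lists the same three regions with
periods 12/29/66 and copy totals 9/7/6 — each total includes the one
truncated terminal element, which the scanner reports in the `truncated`
column. `run/orfs.tsv` contains the four planted ORFs at their exact
planted coordinates (e.g. `2071 2670 + 600 nt`) among shorter chance
ORFs, which is normal for dense two-strand genomes; one call
(`19959..201`) spans the origin. The composition report

```
scope      length_bp  percent_of_genome  at_percent
genome     20000      100.0              58.4
6994:7149  156        0.8                55.1
```

shows the interval arithmetic: 6,994–7,149 inclusive is 156 bp, the size
of the conserved non-coding element (CNE) of alphabaculoviruses.

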