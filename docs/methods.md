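# Methods

This note documents the models and procedures implemented in `annotqc`,
the parameter choices that matter, what the synthetic studies emulate,
and the known limitations. Nothing here states a result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinate and I/O conventions

All internal coordinates are 0-based half-open. GFF3 and 12-column hit
files are 1-based inclusive on disk and converted at the I/O boundary
only; BED is already half-open. Non-ACGTN letters are mapped to `N`
with a warning rather than failing, so slightly dirty inputs do not
halt a pipeline. When a gene carries several mRNA isoforms, the first
by file order is used — gene sets are handled without isoforms
throughout. Gene strand is a property of the gene model; exon/CDS/UTR
sub-intervals are unstranded.

## Assembly metrics

NX is the length of the contig at which the descending cumulative sum
first reaches X% of the total; LX is its 1-based rank; auN = Σl²/Σl is
the length-weighted mean contig length (area under the Nx curve). GC%
is computed over A+C+G+T only — the treatment of N in the denominator
is otherwise ambiguous — and printed with two decimals. All printed
roundings are half-away-from-zero, matching how such tables are
conventionally typeset (banker's rounding would print 0.5→0). The
scaffold length filter is strict (`> 35 kb` keeps 35,001 but not
35,000), read directly off the wording "larger than"; the alternative
`≥` cut cannot be distinguished from published scaffold counts alone.

## Transcript-contig QC

**Trimming.** The first and last 5 bases of each contig are removed
(assembler ends are unreliable); contigs shorter than 2·n become empty
and are dropped.

**DUST masking.** Low complexity is scored per 64-base window from
triplet counts: S = 10 · Σ_t c_t(c_t−1)/2 / (w−2). Windows with S > 20
are masked in full and overlapping masked windows merged. This is the
symmetric variant of the DUST statistic; masked-base counts can differ
slightly from NCBI `dustmasker`, whose perfect-interval refinement is
not reproduced — window, threshold and the resulting intervals are
exact and oracle-checked instead. Triplets containing `N` are counted
like any other triplet. The complexity filter then keeps contigs
strictly longer than 150 bp with strictly more than 75% unmasked bases.

**ORFs.** An ORF is a complete ATG→in-frame-stop span on any of the six
frames with at least 100 codons before the stop (configurable). Every
ATG maps to the first in-frame stop after it, so nested ORFs sharing a
stop are all reported; minus-strand ORFs are mirrored into forward
contig coordinates.

**Pair coverage.** A read pair is *consistent* iff the mates are
convergent (leftmost mate on +, rightmost on −) and the outer span is
at most 1,000 bp — the insert bound is a package default, as no
physical library insert is implied by the inputs. Depth is incremented
over the full outer span; transcript-strand votes are tallied from the
orientation of read 1.

**Chimera splitting.** Candidate junctions are maximal runs of depth
exactly 0 spanning ≥ 10 bases (`min_gap` avoids single-base dropouts).
A gap is actionable iff it lies strictly inside the contig and
intersects no ORF and no domain interval; runs touching a contig end
are trimming problems, not fusion junctions, and are reported but not
cut. The gap bases themselves are removed — the junction sequence is
artefactual — and the reported break position is the gap midpoint, so
the sub-contig lengths plus removed gap bases always equal the original
length. Abrupt *non-zero* coverage shifts are not used as break
evidence; only the depth-0 rule is implemented.

**Orientation.** If minus votes strictly exceed plus votes the contig
is reverse-complemented; ties keep the input orientation and are
flagged ambiguous.

## Evidence and gene filtering

Evidence thresholds are all strict inequalities, following "higher
than/more than" phrasing: transcript alignments kept at overlap > 0.80
of the *contig* length (not the alignment span) and identity > 95;
protein matches kept when scoring > 0.9 of their group's best (the best
match itself always survives) and, per protein, > 0.5 of the length
aligned. A single-exon transcript is "sample-specific" when no
transcript from a different sample overlaps it by ≥ 1 base on the same
scaffold and strand — a genomic-overlap reading of cross-sample
support.

The gene cascade applies three rules in order, first match wins:

* **R1** (any gene): exonic repeat coverage > 0.90 **or** a TE tag,
  with no pfam and no blastp hit → REPEAT_TE. The no-hit guard covers
  both branches: a repeat-covered or TE-tagged gene with a domain or
  protein hit is kept. Repeat coverage is computed over the union of
  exonic bases.
* **R2** (intronless only): no supporting protein species, UTR ratio
  UTR/(UTR+CDS) > 0.80 on *spliced* lengths, no hits → UTR_RNA_ONLY.
* **R3** (intronless only): none of (mRNA ≥ 1 **and** protein ≥ 1),
  (mRNA samples ≥ 2), (curated same-species protein), and no hits →
  WEAK_EVIDENCE.

A pfam or blastp hit therefore always rescues a gene; this
monotonicity is asserted as a property test. Multi-exon genes can only
fall to R1. Rules are evaluated per gene, so decisions are independent
of gene order.

## Repeat scanning

Satellite monomers and multi-copy references are found by exact
Smith–Waterman local alignment (match +1, mismatch −1, gap open −2, gap
extend −1) with iterative masking: report the best hit, replace its
scaffold span with `N`, realign, until the best score falls below a
floor. The floor is derived from the reporting thresholds — a gap-free
hit covering fraction c of a probe of length L at identity p scores at
least cL(2p−1) — so no reportable hit can be missed. Occurrence
acceptance is coverage > 0.80 of the probe (coverage is measured on the
probe, the natural reading when variants are described by how much of
the monomer they cover) and identity ≥ 90% (strict/inclusive
respectively, matching the "> / ≥" thresholds). Masking guarantees
pairwise non-overlapping occurrences, and a monotonicity test confirms
that raising the identity cut never adds occurrences. Exact alignment
replaces seeded heuristics (BLAST-style) deliberately: at single-probe
scale it is fast enough and removes seeding nondeterminism; counts are
per masked hit, not per merged interval.

## Comparative genomics

Best hits keep e-value ≤ 1e-10 and take the highest bitscore per query,
breaking ties by lower e-value then lexicographic subject id (a
deterministic, logged choice). RBH pairs are mutual bests. An optional
isoform→gene collapse (best isoform score per gene) is provided for
proteomes distributed at isoform level.

Synteny chaining sorts the positioned pairs of each
(scaffold, chromosome) combination by position on genome A (gene
position = midpoint of the genomic span, since no anchor is canonical)
and greedily extends a chain while B positions stay monotone — the
direction fixed by the chain's first step — and consecutive gaps on
both genomes stay ≤ 1 Mb. Chains under 3 genes are discarded;
orientation is "inverted" when B decreases. Greedy maximal-run
splitting was chosen over LIS-style dynamic programming: at desk scale
it is transparent, and it is verified equal to an exhaustive
whole-chain-revalidating oracle on all inputs up to 12 genes.

Paralog clusters are connected components of the within-species hit
graph after dropping self-pairs and super-threshold e-values
(networkx); genes present in the table but left edgeless are reported
as singletons. Family expansion counts clustered members per family
label and species; a family absent from the second species prints an
"inf" ratio.

The ortholog CDS-length regression is ordinary least squares of
log10(len_B) on log10(len_A) (scipy). Slope and R² are log-base
invariant; the intercept is reported in base 10.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *structure* of a real two-beetle study at
desk scale: 8 scaffolds of 30–60 kb (not hundreds of Mb); satellite
arrays as tandem copies of a fixed 142-bp monomer — a random sequence
shipped as a package constant, standing in for a real satellite whose
sequence is not distributed — with per-copy identity drawn from
85–100%; one scaffold carrying 3 tandem copies of a
mitochondrion-like reference (15,724 bp by default; analyses in the
tests and acceptance script use a 2-kb probe, which exercises the same
code at ~60× less alignment work); 27% intronless genes; a
20-versus-2 expanded family; 500 planted orthologs over 4 scaffold
pairs with 2 interior inversions (2 breakpoints each, so 1 + 2 blocks
on a rearranged pair). Background sequence is i.i.d. uniform ACGT, so
DUST behaviour is predictable and any low-complexity tract is planted
explicitly. Bitscores separate planted bests (≈500) from decoys (≈300)
with additive uniform noise of half-width 5 by default; noise-free mode
(ε = 0) is used wherever a test asserts exact recovery.

Passing these studies shows that each stage implements its rule exactly
and recovers what was planted under its own assumptions. It does *not*
show robustness to real-data phenomena the generators omit: sequencing
error and coverage dips in non-chimeric contigs, repeat-induced
multi-mapping, overlapping genes, trans-splicing, isoform-level hit
structure, satellite higher-order repeats, or NUMT-like partial
insertions. Those require real sequencing data and external aligners,
which are inputs to — not parts of — this package.

Gene models are coordinate containers: at 2,000 genes per synthetic
study, model coordinates may run past the desk-scale scaffold ends; no
analysis in the package reads gene sequence from the scaffold.

## Numerical choices and degenerate inputs

Percent and mean roundings are half-away-from-zero via `decimal`.
Empty contig lists, zero denominators, sub-20-bp probes, fewer than 3
regression pairs and non-positive lengths raise errors rather than
returning sentinels. The UTR ratio is undefined (None) when a gene has
neither CDS nor UTR, in which case the UTR rule cannot fire.
Determinism: every generator draws from a single numpy Generator per
call, seeded from `SimConfig.seed` (sub-generators use fixed offsets),
so equal seeds give byte-identical FASTA/TSV output.

## Problem sizes

The default test and acceptance sizes — 1,000 random length multisets,
200 contigs, 2,000 genes plus 10,000 random evidence draws, 500
orthologs, 100 random graphs and permutations, 100 masked 1-kb
sequences, 45 satellite copies and a 3-copy 2-kb tandem reference —
were chosen so the full suite runs in well under a minute on one core
while every planted structure still occurs many times.
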