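# Methods

## The comparison problem

A personalized reference is a de novo assembly of an individual's normal
genome. Somatic variants called against it and against a population
reference describe the same tumor, but live in different coordinate systems
on locally different sequences: the personal assembly carries that
individual's germline SNVs, indels, and repeat-element insertions (Alu,
LTR, SVA copies, homopolymer run-length differences) that the population
reference lacks. persoma quantifies how the two views correspond: which
somatic calls are identical, which are equivalent up to germline flank
variation, which are questionable (mappable locus, no corresponding call),
and which exist only on one assembly.

## Cross-assembly SNV mapping

Each somatic SNV on the source assembly yields two 101 bp queries: the
reference allele and the alternate allele, each centered in 50 bp of source
flanking sequence. Both queries are aligned to the target assembly and the
best hit of each must agree in scaffold, start, end, and strand.

Two-step criteria: step 1 demands identity ≥ 99 % and alignment length
≥ 101 bp (at most one mismatch across the full window — the alternate
allele's center mismatch uses up that allowance when the target carries the
reference base); SNVs not selected fall to step 2 with 95 % / 95 bp.
Remaining failures are unmapped.

The mapped center is the target base aligned to the query center. It is
projected through the reference-allele hit: the alternate-allele query may
legally explain its center mismatch as an insertion/deletion pair of equal
alignment score, whereas the reference query matches the (normal-genome)
target at the center and places it unambiguously.

Classification against the target assembly's two-caller consensus:

* no call with the matching (strand-adjusted) alternate allele at the
  mapped center → **mapped_no_call**;
* otherwise **identical** when both queries align full-length with zero
  non-center mismatches and no gaps, else **equivalent**.

The identical/equivalent boundary is a design choice: "passed step 1" would
tolerate one flank mismatch, whereas the intended meaning of *equivalent* is
"germline variation present in the flanks". We therefore pin identical to
"zero flank differences" and report the step-1-selected count alongside, so
either reading is checkable from the same output.

## The alignment engine

Queries are short (≤ ~1.7 kb) and targets are assemblies, so the engine is
a seed-and-extend local aligner with an exact k-mer index (k = 11, valid
range 7–15; both strands served by reverse-complement lookup; k-mers
containing N are never indexed). Seeds chain on diagonals within 50 bp;
each chain opens a window padded by the query length, and windows are
scored by a Smith–Waterman/Gotoh dynamic program.

Scoring: match +1, mismatch −2, gap open −2.5, gap extend −2.5 (held as
×2-scaled integers internally, so all comparisons are exact). With equal
open/extend this is a linear gap penalty; the parameters remain separate in
the code. Percent identity is 100 × matches / alignment columns with gap
columns in the denominator. Acceptance of a hit is by identity and length
thresholds — not e-values — matching how the comparison criteria are
stated.

The DP maximizes the pair (score, n_matches) lexicographically, so
"the best location with the maximum number of matching bases" is
well-defined among co-optimal alignments; remaining ties break
deterministically (diagonal before vertical before horizontal in
traceback; smaller target coordinates for the best cell; scaffold name,
then position, in best-hit selection). Up to 10 hits are reported per
query.

The heuristic's contract is oracle equivalence, not implementation detail:
the test suite checks best-hit score, match count, and identity against an
exhaustive full-matrix DP over the entire target (an independent
single-matrix formulation, exact because open = extend) on 500+ random
planted instances, and cross-checks raw optimal scores against Biopython's
`PairwiseAligner` under identical scoring. A seed-count shortcut discards
single-seed chains for queries ≥ 8k bp long; any alignment passing the
identity/length gates retains ≥ 25 exact 11-mers (pigeonhole over ≥ 90
matched columns with ≤ 5 interruptions), so the shortcut cannot lose a
qualifying hit.

## SV operations

**Pre-filters**, in order: PASS only; caller quality floor (20 for
novoBreak-style callsets); IMPRECISE and SHADOWED flags; |SVLEN| ≥ 50 bp
(translocations exempt); intra-chromosomal breakends; region exclusions.
The shipped exclusion set mirrors the benchmark convention: chrX, chrY,
unplaced/unlocalized/decoy scaffolds, chr6p below 58,500,000 and chr16q
above 38,400,000, expressed as comparator rules (a BED exporter converts).

**Type harmonization** pools deletions with repeat/tandem contractions as
DEL and insertions with repeat/tandem expansions as INS (different
assembly-comparison tools notate the same event either way, e.g. the same
668 bp event as a Deletion or a Repeat_contraction); DUP may optionally
pool with INS for reporting.

**Somatic selection** on jointly genotyped tumor/normal records keeps a
call iff rule 1 (normal 0/0; tumor 0/1 or 1/1 with alt ≥ 5 and AF ≥ 0.2) or
rule 2 (normal 0/1; tumor 1/1 with alt ≥ 10, AF ≥ 0.85, and AF difference
≥ 0.45) holds. **Germline subtraction** first reduces the normal-sample set
to records with AF ≥ 0.1 and alt ≥ 5, then vetoes tumor calls with a
type-compatible reduced record within the merge radius. The radius
operationalizes "overlapping", which the selection rules do not define
precisely; we use the same 1000 bp breakpoint distance as merging.
AF thresholds compare with a 1e-9 epsilon so stated boundaries (0.2, 0.85,
0.45, 0.1) are inclusive under floating point.

**Consensus merging** is single-linkage clustering of same-harmonized-type
records whose start and end breakpoints each differ by ≤ 1000 bp
(translocations cluster by both endpoint pairs); clusters with support from
≥ 2 distinct labels survive, records < 50 bp are ignored, and the
representative is the first-label member. Size compatibility within a
cluster is deliberately not enforced. Replicate-support filtering is the
same clustering with support counted over replicates. The contract is a
brute-force pairwise-graph oracle (connected components), checked on random
instances up to 200 records.

**SV cross-mapping** extracts 100 bp flanks abutting the breakpoints (for
insertions, abutting the insertion point; translocations are out of
scope). Both flanks' best hits must pass 98 % / 90 bp on one scaffold, same
strand, in consistent order; the mapped interval spans the inner hit ends
and matches a target SV of compatible harmonized type when both breakpoints
fall within the radius. Every mappable SV ends exactly one of
matched / mapped_without_match / unmapped.

## Mitochondrial comparison

Assembled mitochondrial contigs are arbitrary rotations, possibly
reverse-complemented, of a circular molecule. `rotate_circular_to_anchor`
locates a ≥ 20 bp anchor (e.g. the canonical mitogenome start) in the
doubled contig on either strand, allowing ≤ 2 mismatches — the tolerance is
our choice, small enough that a unique anchor stays unique — and errors if
the anchor is absent or found more than once. Two anchored sequences
(lengths within 1 %) are globally aligned with edlib (Needleman–Wunsch
path); substitution columns are reported in first-sequence coordinates and
indel runs listed separately. Gap placement inside short repeats is
alignment-ambiguous, so tests assert indel content and total length rather
than exact gap coordinates. Gene annotation is an optional user-supplied
interval table; no external database is queried.

## Assembly metrics

Lengths are optionally floored (the evaluation convention drops scaffolds
< 10 kb; the library default is no floor, the CLI default 10 kb), sorted
descending; N50 is the length at which the cumulative sum first reaches
half the post-filter total ("first ≥ half", ties toward smaller L50), L50
its rank, Top-k the sum of the k = 50 longest. Top50 percentages use the
post-filter total, noted in the CLI header.

## Synthetic data: what it emulates, and what it does not

Background sequence is i.i.d. uniform ACGT with configurable GC (default
0.41, human-like). Repeat families default to Alu-like 300 bp, LTR-like
500 bp, SVA-like 1.6 kb consensus motifs; each planted copy diverges by a
per-copy rate drawn from 0.5–2 %, so flank mapping across copies is
non-trivial. The personal genome applies homozygous germline edits (hom-alt
SNVs and indels at rates 1e-3 and 1e-4 per bp; configured SV counts;
personal-only repeat insertions; homopolymer run-length differences of
5–20 bp, echoing observed assembly-vs-reference homopolymer discrepancies)
through an explicit edit script whose coordinate lift is exact and
invertible outside replaced spans. Somatic MAFs draw from a clonal mixture
of 0.5 (het) and 1.0 (hom/LOH), the range where tumor cell-line validation
is meaningful. Caller error models drop truth records at a false-negative
rate, add Poisson false positives, and jitter SV breakpoints with Gaussian
sd (default 30 bp, well inside the 1000 bp merge radius so noise-free
recovery is meaningful, not trivial).

Deliberate placement rules keep the planted truth decodable: SVs separate
by ≥ 2000 bp (twice the merge radius), somatic SVs avoid germline SV
neighborhoods (a somatic call within the radius of a true germline SV
would be correctly, and unrecoverably, subtracted), and flank-germline SNVs
for the cross-mapping study sit ≥ 5 bp from the 101 bp window edges and
≥ 3 bp from the center so local alignment cannot clip them away.

Not emulated: read-level data (no FASTQ/BAM, no sequencing error or
coverage model), heterozygous germline variation in the assembly (the
personal genome is a haploid consensus; het germline variants are recorded
in the truth but do not alter the sequence), segmental duplications,
GC-content structure, and realistic repeat-family phylogenies.
Consequently, passing recovery tests demonstrate the correctness of the
comparison logic under its stated assumptions — not caller performance or
mappability characteristics of real genomes.

## Problem sizes

The shipped study sizes are desk-scale by design: the SNV cross-mapping
recovery study uses a 2 Mb genome pair with 500 planted somatic SNVs
(300 clean / 150 flank-germline / 50 destroyed); somatic SV selection uses
two 1.5 Mb scaffolds with 200 germline and 100 somatic SVs; merging uses
three jittered replicates of ~13 SVs; the mitogenome is 16.5 kb. Genome-
scale counts from deep whole-genome sequencing of real cell lines are not
reproducible at these sizes; the accounting arithmetic over the published
integer inputs is therefore reported separately from the synthetic
recovery measurements.

## Known limitations

* The seed-and-extend engine reports at most one alignment per candidate
  window, so tandem near-duplicate hits inside a single window surface only
  as the best one; distinct windows (distinct diagonal chains) are reported
  separately.
* VCF support covers the modeled fields (SVTYPE/SVLEN/END/IMPRECISE, GT,
  AD, AF and caller-dialect key remapping), not the full specification;
  symbolic small-variant alleles are skipped. END follows the htslib
  padding-base convention END = POS + |SVLEN| for symbolic deletion
  alleles.
* Multi-allelic records split into bi-allelic records on read — the
  natural convention for allele-aware intersection; the comparison outcome
  is insensitive to the choice because intersection keys on normalized
  (chrom, pos, ref, alt).
* The k-mer seed index holds positions for the concatenated assembly in
  memory (~12 bytes/bp); chromosome-scale assemblies fit, but the engine is
  not a whole-genome-to-genome aligner.
* Indel cross-mapping is out of scope (only SNVs map base-precisely);
  translocations are excluded from SV cross-mapping.
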