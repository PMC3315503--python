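# Methods

## Overview

`domainmine` classifies biosynthetic domain sequence tags by (1) locating
candidate ketosynthase (KS) or condensation (C) domains in translated query
sequence, (2) confirming and delimiting them by exact local alignment against
a class-labelled reference database, (3) inserting the trimmed tags into a
fixed master reference alignment, and (4) reading each tag's functional class
off a joint neighbor-joining tree. This note records the models, the
defaults, and the reasoning behind the genuinely open design choices.

## Reference database and taxonomy

A reference database is a FASTA of domain amino-acid sequences, a TSV of
metadata (`domain_id, domain_type, class_label, pathway_name, pathway_type,
product, gene_accession, literature_ref`), and an aligned-FASTA master
alignment whose ungapped rows must equal the FASTA sequences byte-for-byte.
Class labels are a case-sensitive controlled vocabulary — nine KS classes
(Enediyne, Trans-AT, Cis-AT, Hybrid, Iterative, PUFA, KS1, Type II, FAS) and
eight C classes (LCL, DCL, Starter, Cyclization, Epimerization, Dual E/C,
Modified AA, Hybrid C); unknown labels are hard errors. Only FAS carries
`secondary_metabolism = False`: fatty-acid KS homologs are expected by-catch
of any low-stringency domain screen and the classifier's job is to separate
them from genuine secondary-metabolite signal.

The shipped miniature sets (27 KS domains of 400 aa, 24 C domains of 300 aa;
3 per class) are **synthetic**, generated by `domainmine.synthetic` under
fixed seeds (see `scripts/build_reference_set.py`) with the real taxonomy and
example-product metadata attached. Curated domains from experimentally
characterized pathways cannot be redistributed here; the synthetic families
reproduce the property the pipeline actually depends on — clean class-level
clade structure (within-class mean identity ≈ 0.85, between-class ≈ 0.36) —
at a size where every test runs offline in seconds. Consequences of this
substitution are discussed under Limitations.

## Detection (prescreen)

Genomic input is translated in all six frames (ambiguous codons → X, stops
kept as `*`) and scanned with a position-specific scoring profile built from
the master alignment: per-column log₂-odds of the 20 amino acids against a
uniform background, pseudocount weight 1.0, columns with >50% gaps dropped.
Stops score −10⁴, so windows never span a frame break.

A candidate window is the profile width; windows are scored at **every**
position. A coarser stride was considered and rejected: a position-specific
profile has no shift tolerance, so a window off-register with the true domain
start scores like background, and any stride > 1 misses domains whose start
falls between sample points. The column-sliced implementation makes the full
scan cheap (a 1 Mb genome, all six frames, scans in a few seconds).

Significance is empirical: a Gumbel(μ, β) is moment-matched to the maximum
window score of `n_random = 300` i.i.d. background sequences of 2,000
residues (seeded; β ≤ 0 is rejected). A region's E-value is the Gumbel tail
probability scaled by dataset size, `E = p_tail · (total translated residues
/ calibration length)`, mirroring database-size E-value semantics. The
default cutoff is E ≤ 10⁻⁵. Overlapping above-cutoff windows are merged and
the merged region takes its best window's span, giving coordinates accurate
to a few residues on substitution-divergent domains. Minimum candidate
length defaults to 150 aa (KS) / 100 aa (C).

## Search and E-values

Candidates (and direct protein/short-nucleotide queries) are aligned to every
reference domain with an exact Smith–Waterman dynamic program: BLOSUM62,
affine gaps with open 11 / extend 1 (a gap of length *g* costs 11 + *g*).
Traceback ties resolve diagonal > up > left and equal-scoring hits order by
subject id, so output is bit-reproducible. E-values use the extreme-value
form `E = K·m·n·e^(−λS)`; (λ, K) are fitted once per scoring scheme by
moment-matching a Gumbel to optimal local scores of 400 random length-200
sequence pairs (seed 271828) and cached as package data (`λ ≈ 0.24`,
`K ≈ 0.042` for BLOSUM62/11/1). These E-values are calibrated to order of
magnitude, which is all the pipeline's two thresholds require: E ≤ 10⁻⁸ for
direct queries (a configuration default, deliberately conservative) and the
loose E ≤ 1 for confirming prescreened candidates, where the prescreen has
already paid the multiple-testing cost.

## Trimming and deduplication

Tags are cut at best-hit coordinates (pad 0 by default — the match span *is*
the tag), one tag per confirmed region, serials assigned in coordinate order
(`contig_1, contig_2, …`). Tags on the same frame overlapping by more than
50% of the shorter tag collapse to the better E-value. Deduplication is off
for direct input and **exact** (byte-identical collapse) on the genomic path
by default; a greedy longest-first clustering mode (identity threshold 0.95)
is available for redundancy-aware diversity counts, with the redundancy map
retained so nothing is silently lost.

## Alignment insertion

Each tag is aligned to the master alignment's column profile (all columns
retained here, so coordinates are preserved) by a three-state global dynamic
program with free end deletions: residue-in-column, column-deleted (cost
scaled by column occupancy, so sparse columns are cheap to skip), and
residue-dropped. Gap penalties are 5.5 bits open / 0.5 bits extend — the
BLOSUM62 11/1 penalties expressed on the profile's bit scale. Query residues
that would require new columns are dropped and logged, never inserted: the
reference alignment is a frozen coordinate system, and every output row has
exactly its column count. Tags placing <30% of their residues are flagged
unalignable, excluded from the tree, and reported. Because each tag is
aligned independently to the same profile, insertion order cannot affect any
row.

## Tree and classification

Pairwise distances are Poisson-corrected (−ln(1−p)) mismatch fractions over
mutually ungapped columns (pairwise deletion, because tags are fragments of
the master coordinate system); pairs sharing <20 columns get the matrix
maximum and are flagged. The tree is classic neighbor joining — deterministic
tie-breaking by smallest leaf-label pair, negative branch lengths clamped to
zero with the deficit moved to the sister branch — midpoint-rooted for
readout. NJ was chosen over likelihood methods because it is exact on
additive inputs, self-contained, O(n³) is ample at desk scale, and the
tree's only consumer (clade majority vote) is robust to the substitution;
the tests verify exact topology recovery on additive matrices and agreement
with an independent NJ implementation.

Classification walks from the tag's leaf rootward to the smallest clade
containing at least one reference leaf and takes the majority class of the
reference leaves in it; the call is accepted when the majority fraction is ≥
0.8 (one stray reference leaf in a small clade does not block a call),
otherwise the tag is `unclassified`. The novelty flag is set when the tag is
unclassified **or** its patristic distance to the nearest reference exceeds
the 95th percentile of within-class reference distances measured on the same
tree — i.e. the tag is more divergent than the reference set's own spread.
This formalizes what a practitioner does by eye on the tree, while the
report keeps support, nearest reference, and distance so the automatic call
can be audited. The best-hit class is kept as a provisional call, and a
`reclassified` flag marks tags whose tree call overrides it.

## Synthetic data generator

Families are star-of-stars phylogenies: a uniform-random root protein, one
ancestor per class at identity `1 − between/2` to the root (default between
= 0.7), members at identity `1 − within` to their ancestor (default within =
0.08). Substitutions are BLOSUM62-biased (P(b|a) ∝ 2^(S/2)), and the number
of substituted sites is exact, so realized identity is within half a residue
of target; the indel rate defaults to 0 (see Limitations). Query tags are
drawn round-robin across classes from a parent reference at a controlled
identity. Genomes are i.i.d. nucleotide background (GC configurable;
default 0.5) with reverse-translated domains (codon choice biased by the
same GC parameter) planted non-overlapping on random strands and frames,
emitting a BED-compatible truth table of 0-based half-open intervals; a
fragmentation mode cuts replicons into ~244 bp reads to emulate short-read
draft input. Every generator is a pure function of seed and parameters.

Benchmark sizes (chosen once as representative desk-scale problems): the
alignment oracle enumerates ≥1,000 pairs of length ≤6; the NJ oracle uses 50
random 8-leaf additive matrices; detection uses 100 domains at 50–80%
identity in 1 Mb of background plus 1 Mb of clean background for the
false-region rate; classification uses 200 tags at 70% identity; every
shipped reference is re-run leave-one-out.

## Limitations

- **Synthetic references.** Real domain families have rate heterogeneity,
  indel-rich alignments, polyphyletic classes (e.g. the trans-AT and
  iterative sub-lineages), and uneven class sizes; the shipped families have
  none of these. Passing benchmarks therefore demonstrate the machinery —
  not field performance on biological references, which will be bounded by
  the curated database a user supplies.
- **No indel realism in detection benchmarks.** The prescreen scores
  fixed-length ungapped windows, so its sensitivity degrades for domains
  with internal indels relative to the profile register; the generator's
  default indel rate is 0 and the detection claims hold for
  substitution-divergent domains. Indel-containing domains are still
  recoverable through the confirmation search (Smith–Waterman is gapped),
  at reduced prescreen sensitivity.
- **E-values are calibrated, not analytic.** Both the profile-scan Gumbel
  and the (λ, K) pair come from finite Monte-Carlo fits; treat E-values as
  order-of-magnitude quantities.
- **Degenerate inputs.** Queries shorter than one codon translate to empty
  frames; frames shorter than the profile are skipped; trees require ≥3
  rows; a reference database must cover every class only if you want
  every class callable (empty classes warn, not fail).
- Sub-lineage resolution within polyphyletic classes, substrate-specificity
  prediction, and metabolite structure inference are out of scope.
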