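# Methods

## Problem and model

A scaffold is a string over {A, C, G, T, N}; every maximal N-run is a
gap whose length is the scaffolder's estimate of the missing sequence.
`gapclose` treats gap filling as *constrained bidirectional greedy
extension*: grow sequence inward from both gap edges using only reads
whose pairing places them inside the gap, and accept the result only
if the two extensions merge into an insertion of approximately the
estimated size. The method deliberately does **not** build a local De
Bruijn assembly of the recruited reads: greedy per-base extension with
consume-on-use k-mers plus the external size constraint is what makes
collapsed tandem repeats detectable rather than silently assembled
short.

Assumptions:

- Gap lengths are within the reach of the insert size — a mate can only
  be recruited to a gap its window covers, so gaps much longer than the
  largest insert remain open or partial by construction.
- Insert sizes are roughly symmetric around the library mean; the
  recruitment window uses a fixed fractional deviation, not a fitted
  distribution.
- Errors in reads are substitutions at the few-percent level; there is
  no indel-aware alignment anywhere in the core (the anchorer verifies
  reads ungapped, extension votes per base).
- The scaffold's non-gap sequence is mostly correct; only the ±t bases
  at gap edges are distrusted (trimmed and re-derived).

## Pipeline stages and parameters

| Parameter | Default | Meaning |
|---|---|---|
| t | 10 nt | flank bases trimmed into each gap side before anything else |
| m | 29 nt | edge overlap for extension; k-mer size k = m + 1 = 30 |
| o | 2 | minimum k-mer count behind the winning overhang base |
| r | 0.7 | minimum fraction of overhang support the winner must carry |
| n | 10 nt | minimum suffix/prefix overlap to merge the two extensions |
| d | 50 nt | maximum \|insertion − expected\| for an accepted closure |
| i | 10 | maximum global iterations (re-align → re-recruit → re-fill) |
| seed_len | 30 nt | anchor seed length of the built-in mapper |
| max_mismatch_frac | 0.04 | anchor verification mismatch budget per read |

The low-coverage setting o = 1, r = 0.5 trades accuracy for closures
on thin data; r = 0.5 is accepted as a valid ratio because exact ties
are always refused by the uniqueness rule regardless of r.

**Expected length accounting.** A gap's `expected_len` is its original
N-count plus the flank bases actually trimmed. The size test compares
the full replacement of the enlarged interval against this value, so a
size-exact closure conserves scaffold length. Trims between two nearby
gaps always leave at least one separating base so gaps never merge,
which keeps per-gap identity stable across iterations; at scaffold
ends the whole flank may be consumed (such gaps then lack an
extensible flank and stay open).

**Recruitment.** Mate 1 is anchored first; if unplaceable, mate 2 is
tried with mate 1 becoming the recruit. Anchors must be *uniquely*
best — multi-mapped anchors are discarded entirely because they would
recruit reads from repeat copies, the dominant failure mode of gap
closing. RF (mate-pair) libraries are normalized to FR by reverse
complementing both mates on input, so one window formula serves both.
The insert size convention is outer (5'-to-5') distance. A recruited
mate may serve several gaps if its window spans them; downstream
coverage and ratio thresholds absorb the noise.

**Extension.** Recruited reads are k-merized on both strands, so every
closure decision is invariant under reverse complementing any read.
Edges alternate strictly L, R, L, R (skipping a stalled side), with a
closure test after every incorporated base. Incorporation consumes all
copies of the used k-mer; when both edges stall, the store is rebuilt
once from all reads and extension resumes, so a k-mer spent early on
one side can still serve the other. Because every step consumes a
distinct k-mer key, extension length is bounded by the store size even
on adversarial cyclic k-mer sets; an explicit per-side cap of
`expected_len + d` additionally bounds work, since any longer
extension could only produce size-vetoed merges.

**Merging.** All suffix/prefix overlaps x ≥ n between the two
extensions are enumerated; among candidate insertions within d of the
expected length the closest wins, ties preferring the larger overlap.
Overlap is restricted to the extensions themselves — flank sequence is
never consumed by the merge.

**Iteration.** Trimming happens in the first iteration only: later
rounds operate on edges produced and vetted by the tool itself, and
re-trimming would erode confirmed sequence. Iterations stop early when
a round inserts zero nucleotides; converged output is a fixed point of
the pipeline. Partial extensions are written into the scaffold with at
least one N retained, so an unclosed gap stays detectable and its
remaining N-run length is the next round's expected length.

**Failure reasons.** A never-closed gap reports the most diagnostic
signal seen across all iterations: `SIZE_MISMATCH` if any merge
existed but was vetoed purely by the size constraint (sticky across
rounds — later rounds merely re-confirm k-mer exhaustion), otherwise
`AMBIGUOUS` (vote tie or weak majority, the repeat signature), then
`NO_COVERAGE`, then `NO_OVERLAP`; `NO_READS` when recruitment found
nothing.

## Built-in anchorer

The external-aligner step is replaced by a deterministic seed-and-
verify mapper: exact lookup of the read's first `seed_len` bases (on
the read and its reverse complement) against an index of all N-free
scaffold windows, then ungapped full-length verification with at most
`floor(0.04 × read length)` mismatches. The uniquely best-scoring
locus wins; score ties across distinct loci mean "unplaced". SAM
ingestion (primary records only, NM tag as mismatch count) is
available for users who prefer an external aligner; the recruitment
logic downstream is identical.

## Synthetic data and what tests show

The simulator emulates the essentials of a wgsim-style run: i.i.d.
reference bases at a set GC, uniform fragment starts, rounded-normal
fragment lengths truncated at [2 × read length, contig end], FR pairs
as fragment prefix / reverse-complemented suffix, i.i.d. substitution
errors and constant qualities. It does **not** simulate read indels,
quality-dependent errors, coverage bias, chimeras or adapter
artefacts; passing the suite therefore demonstrates the algorithm's
correctness and its guardrails under the stated error model, not
robustness to platform-specific artefacts in real libraries. Gap-size
misestimation is modelled by emitting an N-run longer or shorter than
the masked truth.

The evaluator locates each gap in the output via 30 bp reference
anchors placed just outside the modifiable zone (gap ± t), globally
aligns the realized region to the truth with unit edit costs (edlib),
counts mismatch columns as SNPs and runs of gap columns as indel
events split at 5 bp. Event counts are properties of one optimal
alignment; where equal-cost alignments fragment an indel differently,
the total error columns still equal the edit distance (asserted
against an independent quadratic DP in the tests). Structural misjoin
detection is out of scope. A realized region still containing N counts
as OPEN when at least the originally masked length remains, else
PARTIAL.

## Benchmark scenario sizes

The canonical scenarios (`gapclose.datasets`) use a 100 kb genome with
20 gaps of 20–250 bp at 40× for recovery and noise measurements, 50
size-perturbed gaps (offset +60 = d + 10) on a 119 kb genome, one
repeat-bearing gap (40 bp repeat copies flanking a 70 bp unique core)
on 30 kb, and 8 gaps at 10× for the threshold-monotonicity comparison.
These sizes give stable rates (binomial noise ≤ one gap) while keeping
any full run in seconds on a single core.

## Known limitations

- Gaps longer than the insert reach cannot be closed, only narrowed.
- Heterozygous or polyploid data will trip the majority-vote ratio and
  leave edges AMBIGUOUS; there is no dual-path extension.
- The built-in anchorer is substitution-only; reads spanning true
  indels relative to the scaffold will not anchor and are lost to
  recruitment.
- The size constraint inherits the scaffolder's gap-size estimate; a
  badly wrong estimate vetoes a correct reconstruction (reported as
  SIZE_MISMATCH), which is the intended conservative behaviour.
- Repetitive flanks suppress recruitment entirely (anchors become
  ambiguous), yielding NO_READS/NO_COVERAGE rather than AMBIGUOUS.
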