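# gapclose

Close intra-scaffold gaps in draft genome assemblies using paired short
reads.

Draft assemblies from short-read sequencing are usually delivered as
*scaffolds*: contigs ordered and oriented by paired-read linkage and
joined by runs of `N` whose length estimates the missing sequence.
`gapclose` fills these N-runs directly from the read data, for anyone
finishing a bacterial or small eukaryotic genome who wants to avoid
closing gaps one Sanger reaction at a time.

## Method

For each library with insert size *I* and allowed deviation *v*,
`gapclose`:

1. **Trims** up to *t* bases (default 10) off both flanks of every gap
   — contig ends bordering a gap frequently carry misassembled bases —
   and adds them to the expected insertion length.
2. **Anchors** one mate of each pair to the scaffolds (built-in
   deterministic seed-and-verify mapper, or placements from an external
   aligner via SAM) and **recruits** the other mate to every gap that
   intersects its predicted position window: `[s + (1−v)I − ℓ,
   s + (1+v)I)` for a forward anchor at *s* and mate length ℓ, mirrored
   for reverse anchors. Only uniquely placed anchors count; multi-mapped
   anchors would recruit reads from repeat copies.
3. **Extends** both gap edges inward, one overhang base at a time, from
   the k-mers (k = m + 1, default 30) of the recruited reads on both
   strands. A base is incorporated only if its best-supported k-mer has
   count ≥ *o* (default 2) and carries a fraction ≥ *r* (default 0.7) of
   all support; the used k-mer is then consumed. Ties and weak
   majorities stall the edge.
4. **Merges** the two extensions when they share a suffix/prefix overlap
   of ≥ *n* bases (default 10) *and* the resulting insertion is within
   *d* bases (default 50) of the expected gap length. A merge that
   exists but violates the size constraint is rejected — the defining
   safeguard against collapsed repeats.
5. **Iterates** the whole procedure (re-align, re-recruit, re-fill) up
   to *i* times (default 10), stopping early at a fixed point.

Unclosed gaps keep whatever partial extensions were vetted, with the
unresolved middle left as `N`, and are reported with a diagnostic
reason (`NO_READS`, `NO_COVERAGE`, `AMBIGUOUS`, `NO_OVERLAP`,
`SIZE_MISMATCH`).

The package also ships a truth-tracked simulator
(`gapclose.simulate`): reference genome → N-masked scaffolds →
wgsim-style paired reads, plus an evaluator that aligns every realized
fill back to the truth and classifies errors into SNPs and indel
events (≤ 5 bp / > 5 bp).

## Worked example

Generate a 30 kb genome with 8 gaps (20–240 bp), simulate a 30× 2×70 bp
library (insert 300 ± 30), and close the gaps:

```python
from gapclose import datasets
from gapclose.io_formats import write_fasta

sc = datasets.low_coverage_scenario(".", seed=3, coverage=30)
write_fasta(((s.id, s.seq) for s in sc.scaffolds), "scaffolds.fasta")
lib = sc.library
open("libraries.txt", "w").write(
    f"{lib.name} {lib.files[0]} {lib.files[1]} 300 0.25 FR\n")
```

```
$ gapclose -s scaffolds.fasta -l libraries.txt -b demo
INFO gapclose: parameters: t=10 m=29 k=30 o=2 r=0.7 n=10 d=50 i=10
INFO gapclose: iteration 1: closed=8 inserted=880 remaining=0 gap_length=0
```

All 8 gaps closed in one iteration; 880 nucleotides were inserted (the
720 masked bases plus 2 × 10 trimmed flank bases per gap, all
re-derived from read evidence). The per-gap report:

```
$ head -4 demo.gaps.tsv
scaffold_id  gap_start  gap_end  expected_len  status  filled_len  remaining_n  overlap_len  reason
scaffold_1   3000       3020     40            CLOSED  40          0            10           OK
scaffold_1   6200       6250     70            CLOSED  70          0            10           OK
scaffold_1   9400       9500     120           CLOSED  120         0            10           OK
```

Each row is one original gap: its input coordinates, the expected
insertion length (N-run plus trims), the inserted length, and the
extension overlap used for the merge. `demo.summary.txt` shows the
assembly-level before/after metrics (gap count 8 → 0, total gap length
720 → 0, N50 unchanged); `demo.gapfilled.fasta` is the closed assembly.

The library file has six whitespace-separated columns: `name fileA
fileB insert_size deviation orientation` (`FR` = paired-end, `RF` =
mate pair; use `sam:<path> -` for the two file columns to supply
external SAM placements instead of raw reads).

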