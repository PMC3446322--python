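"""Synthetic, truth-tracked test data and closure evaluation.

The generator builds a random reference genome, derives scaffolds from
it by masking stated intervals with N (optionally misreporting the
N-run length, to exercise the size constraint), and emits wgsim-style
paired-end reads: uniform fragment starts, near-normal fragment
lengths, fixed read length, i.i.d. per-base substitution errors and
constant FASTQ qualities.  Reads carry no simulated indels — the
generator's job is controlled truth for the closing algorithm, whose
extension model is substitution-only.

The evaluator compares each realized gap region in a filled assembly
against the recorded truth with a unit-cost global edit alignment and
classifies differences into SNPs and indel events (split at 5 bp),
the standard small-error taxonomy for assembly quality assessment.
Structural misjoin detection is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np

from .model import Scaffold, revcomp

__all__ = [
    "simulate_genome",
    "make_gapped_scaffolds",
    "simulate_read_pairs",
    "evaluate_closure",
    "GapTruth",
    "TruthRegistry",
    "GapEvaluation",
]

_BASES = np.array(list("ACGT"))


def simulate_genome(
    length: int,
    gc: float = 0.5,
    rng_seed: int = 0,
    repeat: tuple[int, int, int] | None = None,
) -> str:
    """Random genome with i.i.d. bases at the given GC fraction.

    ``repeat=(src_start, length, dst_start)`` optionally copies one
    substring over another locus, for constructing repeat-failure
    scenarios.  Deterministic for a fixed seed.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome = "".join(rng.choice(_BASES, size=length, p=probs))
    if repeat is not None:
        src, rep_len, dst = repeat
        if not (0 <= src <= src + rep_len <= length and 0 <= dst <= dst + rep_len <= length):
            raise ValueError("repeat interval out of genome bounds")
        genome = genome[:dst] + genome[src : src + rep_len] + genome[dst + rep_len :]
    return genome


@dataclass
class GapTruth:
    """Truth for one masked gap."""

    scaffold_id: str
    scaffold_start: int  # N-run interval on the emitted scaffold
    scaffold_end: int
    ref_start: int  # masked interval on the reference
    ref_end: int
    true_seq: str
    size_offset: int = 0  # N-run length minus true length


@dataclass
class TruthRegistry:
    """Reference sequence plus per-gap truth records."""

    reference: str
    gaps: list[GapTruth] = field(default_factory=list)


def make_gapped_scaffolds(
    genome: str,
    gap_specs: Sequence[tuple],
    rng_seed: int = 0,
    scaffold_id: str = "scaffold_1",
    min_separation: int = 30,
) -> tuple[list[Scaffold], TruthRegistry]:
    """Mask intervals of the genome with N and record the truth.

    ``gap_specs`` holds ``(start, length)`` tuples, optionally with a
    third element: an offset added to the emitted N-run length to
    emulate a scaffolder's imperfect gap-size estimate (the true
    sequence is unchanged).  Intervals must be in order, within
    bounds, and separated by at least ``min_separation`` bases.
    """
    registry = TruthRegistry(reference=genome)
    pieces: list[str] = []
    cursor = 0
    scaffold_pos = 0
    for spec in gap_specs:
        if len(spec) == 2:
            start, length = spec
            offset = 0
        else:
            start, length, offset = spec
        end = start + length
        if not (0 <= start < end <= len(genome)):
            raise ValueError(f"gap ({start}, {length}) out of genome bounds")
        if start - cursor < min_separation:
            raise ValueError(
                f"gap at {start} too close to previous gap/scaffold start "
                f"(needs >= {min_separation} separating bases)"
            )
        if length + offset < 1:
            raise ValueError(f"gap at {start}: N-run length would be < 1")
        pieces.append(genome[cursor:start])
        scaffold_pos += start - cursor
        n_run = length + offset
        pieces.append("N" * n_run)
        registry.gaps.append(
            GapTruth(
                scaffold_id=scaffold_id,
                scaffold_start=scaffold_pos,
                scaffold_end=scaffold_pos + n_run,
                ref_start=start,
                ref_end=end,
                true_seq=genome[start:end],
                size_offset=offset,
            )
        )
        scaffold_pos += n_run
        cursor = end
    pieces.append(genome[cursor:])
    scaffold = Scaffold(scaffold_id, "".join(pieces))
    return [scaffold], registry


def simulate_read_pairs(
    genome: str,
    coverage: float,
    read_len: int,
    insert_mean: float,
    insert_sd: float,
    error_rate: float,
    orientation: str,
    rng_seed: int,
    out1: str,
    out2: str,
) -> tuple[str, str]:
    """Write a wgsim-style paired-end library as two FASTQ files.

    ``round(coverage * |genome| / (2 * read_len))`` pairs are drawn:
    uniform fragment start, fragment length from a rounded normal
    truncated to ``[2 * read_len, |genome| - start]``; read 1 is the
    fragment prefix and read 2 the reverse complement of its suffix
    (FR).  RF mode reverse complements both mates of the FR pair.
    Substitution errors are i.i.d. per base; qualities are constant
    (offset-33 'I').  Deterministic for a fixed seed.
    """
    glen = len(genome)
    if glen < insert_mean:
        raise ValueError("genome shorter than insert_mean")
    if not (0.0 <= error_rate < 1.0):
        raise ValueError("error_rate must lie in [0, 1)")
    if orientation not in ("FR", "RF"):
        raise ValueError("orientation must be FR or RF")
    if 2 * read_len > glen:
        raise ValueError("genome shorter than one fragment (2 * read_len)")

    n_pairs = round(coverage * glen / (2 * read_len))
    rng = np.random.default_rng(rng_seed)
    starts = rng.integers(0, glen - 2 * read_len + 1, size=n_pairs)
    frags = np.rint(rng.normal(insert_mean, insert_sd, size=n_pairs)).astype(int)
    frags = np.maximum(frags, 2 * read_len)
    frags = np.minimum(frags, glen - starts)

    qual = "I" * read_len
    with open(out1, "w") as fh1, open(out2, "w") as fh2:
        for idx in range(n_pairs):
            s = int(starts[idx])
            f = int(frags[idx])
            r1 = genome[s : s + read_len]
            r2 = revcomp(genome[s + f - read_len : s + f])
            if error_rate > 0.0:
                r1 = _mutate(r1, error_rate, rng)
                r2 = _mutate(r2, error_rate, rng)
            if orientation == "RF":
                r1, r2 = revcomp(r1), revcomp(r2)
            fh1.write(f"@sim_{idx}/1\n{r1}\n+\n{qual}\n")
            fh2.write(f"@sim_{idx}/2\n{r2}\n+\n{qual}\n")
    return out1, out2


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
    if hits.size == 0:
        return seq
    out = list(seq)
    for p in hits:
        base = out[p]
        choices = [b for b in "ACGT" if b != base]
        out[p] = choices[int(rng.integers(0, 3))]
    return "".join(out)


@dataclass
class GapEvaluation:
    """Per-gap comparison of the realized fill against the truth."""

    scaffold_id: str
    ref_start: int
    ref_end: int
    status: str  # PERFECT | CLOSED_WITH_ERRORS | PARTIAL | OPEN
    snps: int = 0
    indels_le5: int = 0
    indels_gt5: int = 0
    realized_len: int = 0
    true_len: int = 0


def _classify_cigar(cigar: str) -> tuple[int, int, int]:
    """(snps, indel events <= 5 bp, indel events > 5 bp) from an extended CIGAR."""
    snps = 0
    le5 = 0
    gt5 = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        length = int(num)
        num = ""
        if ch == "X":
            snps += length
        elif ch in ("I", "D"):
            if length <= 5:
                le5 += 1
            else:
                gt5 += 1
        elif ch != "=":
            raise ValueError(f"unexpected CIGAR op {ch!r}")
    return snps, le5, gt5


def evaluate_closure(
    scaffolds: Iterable[Scaffold],
    registry: TruthRegistry,
    trim: int = 10,
    anchor_len: int = 30,
) -> tuple[list[GapEvaluation], dict[str, int]]:
    """Compare every gap's realized region against its recorded truth.

    Each gap is located in the (possibly rewritten) scaffold by its
    flanking anchor sequences, taken from the reference just outside
    the zone the pipeline may modify (gap ± ``trim``).  The realized
    region between anchors is globally aligned to the true region with
    unit edit costs; mismatch columns count as SNPs and runs of gap
    columns as indel events, split at 5 bp.  Regions still containing
    N are PARTIAL, or OPEN when at least the originally masked length
    remains unresolved.  A missing anchor means the assembly does not
    match the registry and raises.
    """
    by_id = {sc.id: sc.seq for sc in scaffolds}
    ref = registry.reference
    evaluations: list[GapEvaluation] = []
    totals = {
        "gaps": 0,
        "perfect": 0,
        "closed_with_errors": 0,
        "partial": 0,
        "open": 0,
        "snps": 0,
        "indels_le5": 0,
        "indels_gt5": 0,
    }
    cursors: dict[str, int] = {}
    for gap in registry.gaps:
        if gap.scaffold_id not in by_id:
            raise ValueError(f"registry scaffold {gap.scaffold_id!r} not in assembly")
        seq = by_id[gap.scaffold_id]
        cursor = cursors.get(gap.scaffold_id, 0)

        left_a_start = max(0, gap.ref_start - trim - anchor_len)
        left_anchor = ref[left_a_start : max(0, gap.ref_start - trim)]
        right_anchor = ref[gap.ref_end + trim : gap.ref_end + trim + anchor_len]

        if left_anchor:
            lpos = seq.find(left_anchor, cursor)
            if lpos < 0:
                raise ValueError(
                    f"{gap.scaffold_id}: left anchor of gap at ref {gap.ref_start} "
                    "not found — assembly does not match registry"
                )
            realized_start = lpos + len(left_anchor)
        else:
            realized_start = cursor
        if right_anchor:
            rpos = seq.find(right_anchor, realized_start)
            if rpos < 0:
                raise ValueError(
                    f"{gap.scaffold_id}: right anchor of gap at ref {gap.ref_start} "
                    "not found — assembly does not match registry"
                )
            realized_end = rpos
            cursors[gap.scaffold_id] = rpos + len(right_anchor)
        else:
            realized_end = len(seq)
            cursors[gap.scaffold_id] = len(seq)

        realized = seq[realized_start:realized_end]
        true_region = ref[max(0, gap.ref_start - trim) : gap.ref_end + trim]

        ev = GapEvaluation(
            scaffold_id=gap.scaffold_id,
            ref_start=gap.ref_start,
            ref_end=gap.ref_end,
            status="OPEN",
            realized_len=len(realized),
            true_len=len(true_region),
        )
        masked_len = gap.scaffold_end - gap.scaffold_start
        if "N" in realized:
            n_count = realized.count("N")
            ev.status = "OPEN" if n_count >= masked_len else "PARTIAL"
        elif realized == true_region:
            ev.status = "PERFECT"
        else:
            ev.status = "CLOSED_WITH_ERRORS"
            aln = edlib.align(realized, true_region, mode="NW", task="path")
            ev.snps, ev.indels_le5, ev.indels_gt5 = _classify_cigar(aln["cigar"])
        evaluations.append(ev)

        totals["gaps"] += 1
        totals[ev.status.lower() if ev.status != "CLOSED_WITH_ERRORS" else "closed_with_errors"] += 1
        totals["snps"] += ev.snps
        totals["indels_le5"] += ev.indels_le5
        totals["indels_gt5"] += ev.indels_gt5
    return evaluations, totals
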