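"""The gap-closing core: edge trimming, k-mer voting extension, merging.

Each gap is first enlarged by trimming up to ``t`` bases off both
flanks (contig ends bordering a gap often carry misassembled bases).
Reads recruited to the gap are split into k-mers on both strands.  The
gap is then grown inward from each edge one overhang nucleotide at a
time: a base is incorporated only when the k-mers supporting it are
sufficiently many (``o``) and sufficiently dominant (ratio ``r``), and
the supporting k-mer is consumed on use.  After every incorporation
the two extensions are tested for a suffix/prefix merge of at least
``n`` bases whose resulting insertion matches the expected gap length
within ``d`` nucleotides.  When both edges stall, the k-mer store is
rebuilt once from all reads and extension resumes; a second stall ends
the attempt.

No randomness anywhere: identical inputs give identical closures.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .model import (
    ClosureResult,
    GapInterval,
    GapRecord,
    GapStatus,
    KmerStore,
    Parameters,
    Reason,
    Scaffold,
    revcomp,
)

__all__ = [
    "trim_gap_edges",
    "build_kmer_store",
    "extend_step",
    "extend_edge",
    "try_close",
    "fill_gap",
    "apply_closure",
]


def trim_gap_edges(
    scaffold: Scaffold, gaps: Sequence[GapInterval], t: int
) -> tuple[Scaffold, list[GapRecord]]:
    """Enlarge every internal gap by up to ``t`` flank bases per side.

    The trimmed bases are replaced by N (scaffold length is unchanged)
    and counted into the gap's ``expected_len`` — they must be
    re-derived from read evidence during extension.  Trims are limited
    by flank availability: toward a scaffold end the whole flank may be
    consumed, while between two gaps at least one separating base is
    always kept on the shared flank so gaps never merge.  Terminal
    N-runs get untrimmed records flagged unfillable.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    seq = scaffold.seq
    records: list[GapRecord] = []
    pieces = list(seq)
    prev_end = 0  # right edge of the previous gap's enlarged interval
    prev_was_gap = False
    for j, gap in enumerate(gaps):
        if gap.terminal:
            records.append(
                GapRecord(
                    scaffold_id=scaffold.id,
                    start=gap.start,
                    end=gap.end,
                    expected_len=gap.end - gap.start,
                    terminal=True,
                )
            )
            prev_end = gap.end
            prev_was_gap = True
            continue
        # Left trim: up to the previous gap's enlarged edge (keeping a
        # one-base separator) or to the scaffold start.
        avail_left = gap.start - prev_end
        tl = min(t, max(0, avail_left - 1)) if prev_was_gap else min(t, avail_left)
        # Right trim: share the flank with the next gap, reserving it a
        # fair portion, or run to the scaffold end.
        if j + 1 < len(gaps):
            allowance = max(0, gaps[j + 1].start - gap.end - 1)
            tr = min(t, max(allowance - t, allowance // 2))
        else:
            tr = min(t, len(seq) - gap.end)
        start = gap.start - tl
        end = gap.end + tr
        for p in range(start, gap.start):
            pieces[p] = "N"
        for p in range(gap.end, end):
            pieces[p] = "N"
        records.append(
            GapRecord(
                scaffold_id=scaffold.id,
                start=start,
                end=end,
                expected_len=(gap.end - gap.start) + tl + tr,
            )
        )
        prev_end = end
        prev_was_gap = True
    return Scaffold(scaffold.id, "".join(pieces)), records


def build_kmer_store(reads: Iterable[str], k: int) -> KmerStore:
    """Multiset of every N-free k-window of the reads, both strands."""
    store = KmerStore(k)
    for seq in reads:
        store.add_read(seq)
    return store


def extend_step(
    edge_mer: str, store: KmerStore, o: int, r: float
) -> tuple[str | None, Reason]:
    """Vote on the single overhang base following an m-long edge.

    Counts support for ``edge_mer + B`` over B in {A,C,G,T}.  The top
    base wins when its count reaches ``o``, it holds at least fraction
    ``r`` of the total support and the maximum is unique; its k-mer is
    then removed from the store (all copies).  Failures report
    NO_COVERAGE (count below ``o``) or AMBIGUOUS (tie or ratio fail).
    """
    counts = [(store.count(edge_mer + b), b) for b in "ACGT"]
    total = sum(c for c, _ in counts)
    best_c, best_b = max(counts)
    if best_c < o:
        return None, Reason.NO_COVERAGE
    if sum(1 for c, _ in counts if c == best_c) > 1:
        return None, Reason.AMBIGUOUS
    if best_c / total < r:
        return None, Reason.AMBIGUOUS
    store.remove_all(edge_mer + best_b)
    return best_b, Reason.OK


def extend_edge(
    flank_suffix: str, store: KmerStore, params: Parameters, cap: int
) -> tuple[str, Reason]:
    """Grow an extension rightward from a flank until stalled or capped.

    ``flank_suffix`` must provide at least ``m`` N-free trailing bases,
    else nothing grows (NO_COVERAGE).  Right gap edges are handled by
    the caller via reverse complement.  Returns the extension and the
    stall reason (OK when the cap was reached — the cap bounds growth
    on adversarial, e.g. cyclic, k-mer sets).
    """
    m = params.m
    if len(flank_suffix) < m or "N" in flank_suffix[-m:]:
        return "", Reason.NO_COVERAGE
    edge = flank_suffix[-m:]
    ext: list[str] = []
    reason = Reason.OK
    while len(ext) < cap:
        base, reason = extend_step(edge, store, params.o, params.r)
        if base is None:
            break
        ext.append(base)
        edge = edge[1:] + base
        reason = Reason.OK
    return "".join(ext), reason


def try_close(
    left_full: str, right_full: str, expected_len: int, n: int, d: int
) -> ClosureResult:
    """Attempt to merge the two extensions into one insertion.

    Scans every suffix/prefix overlap ``x >= n`` between the left
    extension and the right extension (both in scaffold orientation).
    Each overlap proposes the insertion ``L + R[x:]``; among proposals
    within ``d`` of the expected length the closest wins (ties prefer
    the larger overlap).  Failure reasons: NO_OVERLAP when no overlap
    of length >= n exists, SIZE_MISMATCH when overlaps exist but every
    proposal misses the expected length by more than ``d``.
    """
    L, R = left_full, right_full
    best: tuple[int, int, int] | None = None  # (diff, -x, x)
    found = False
    for x in range(n, min(len(L), len(R)) + 1):
        if L[-x:] == R[:x]:
            found = True
            ins_len = len(L) + len(R) - x
            diff = abs(ins_len - expected_len)
            if diff <= d and (best is None or (diff, -x) < best[:2]):
                best = (diff, -x, x)
    if best is not None:
        x = best[2]
        return ClosureResult(
            status=GapStatus.CLOSED,
            reason=Reason.OK,
            inserted_seq=L + R[x:],
            overlap_len=x,
            left_ext=L,
            right_ext=R,
        )
    return ClosureResult(
        status=GapStatus.OPEN,
        reason=Reason.SIZE_MISMATCH if found else Reason.NO_OVERLAP,
        left_ext=L,
        right_ext=R,
    )


def fill_gap(
    gap: GapRecord,
    reads: Sequence[str],
    params: Parameters,
    left_flank: str,
    right_flank: str,
) -> ClosureResult:
    """Fill one gap from its recruited reads.

    Alternates single-base extension steps on the left then right edge
    (skipping a stalled side), testing for closure after every
    incorporation.  When both edges stall, the k-mer store is rebuilt
    once from all reads (restoring consumed k-mers) and extension
    resumes; the second stall ends the attempt with PARTIAL (some
    extension grown) or OPEN.  Each side's growth is capped at
    ``expected_len + d`` — anything longer necessarily fails the size test.

    The reported failure reason prefers the most diagnostic signal:
    SIZE_MISMATCH if any closure attempt was vetoed purely by the size
    constraint, then AMBIGUOUS, then NO_COVERAGE, then NO_OVERLAP.
    """
    if not reads:
        return ClosureResult(status=GapStatus.OPEN, reason=Reason.NO_READS)
    m = params.m
    cap = gap.expected_len + params.d
    store = build_kmer_store(reads, params.k)

    left_valid = len(left_flank) >= m and "N" not in left_flank[-m:]
    right_valid = len(right_flank) >= m and "N" not in right_flank[:m]
    left_edge = left_flank[-m:] if left_valid else ""
    # The right edge extends leftward in scaffold space; work on the
    # reverse complement so both sides grow rightward.
    right_edge = revcomp(right_flank[:m]) if right_valid else ""

    left_ext: list[str] = []
    right_rc: list[str] = []
    stuck = {
        "L": Reason.NO_COVERAGE if not left_valid else None,
        "R": Reason.NO_COVERAGE if not right_valid else None,
    }
    size_mismatch_seen = False
    rebuilt = False

    while True:
        advanced = False
        for side in ("L", "R"):
            if stuck[side] is not None:
                continue
            ext = left_ext if side == "L" else right_rc
            if len(ext) >= cap:
                stuck[side] = Reason.OK  # capped, not a vote failure
                continue
            edge = left_edge if side == "L" else right_edge
            base, reason = extend_step(edge, store, params.o, params.r)
            if base is None:
                stuck[side] = reason
                continue
            advanced = True
            ext.append(base)
            if side == "L":
                left_edge = edge[1:] + base
            else:
                right_edge = edge[1:] + base
            lseq = "".join(left_ext)
            rseq = revcomp("".join(right_rc))
            res = try_close(lseq, rseq, gap.expected_len, params.n, params.d)
            if res.status is GapStatus.CLOSED:
                return res
            if res.reason is Reason.SIZE_MISMATCH:
                size_mismatch_seen = True
        if stuck["L"] is not None and stuck["R"] is not None:
            if not rebuilt:
                rebuilt = True
                store = build_kmer_store(reads, params.k)
                for side in ("L", "R"):
                    # Re-open sides stalled on votes; invalid flanks and
                    # capped sides stay closed.
                    ext = left_ext if side == "L" else right_rc
                    valid = left_valid if side == "L" else right_valid
                    if valid and len(ext) < cap:
                        stuck[side] = None
                if stuck["L"] is None or stuck["R"] is None:
                    continue
            break
        if not advanced and stuck["L"] is None and stuck["R"] is None:
            break  # pragma: no cover - defensive; sides either advance or stall

    lseq = "".join(left_ext)
    rseq = revcomp("".join(right_rc))
    if size_mismatch_seen:
        reason = Reason.SIZE_MISMATCH
    elif Reason.AMBIGUOUS in stuck.values():
        reason = Reason.AMBIGUOUS
    elif Reason.NO_COVERAGE in stuck.values():
        reason = Reason.NO_COVERAGE
    else:
        reason = Reason.NO_OVERLAP
    status = GapStatus.PARTIAL if (lseq or rseq) else GapStatus.OPEN
    return ClosureResult(status=status, reason=reason, left_ext=lseq, right_ext=rseq)


def apply_closure(scaffold: Scaffold, gap: GapRecord, result: ClosureResult) -> Scaffold:
    """Rewrite the gap's interval according to its closure result.

    CLOSED replaces the N-run with the inserted sequence; PARTIAL
    writes the two extensions with the unresolved middle as N (at
    least one N is always kept so the gap stays detectable); OPEN
    leaves the scaffold untouched.
    """
    if result.status is GapStatus.OPEN:
        return scaffold
    s, e = gap.start, gap.end
    if result.status is GapStatus.CLOSED:
        replacement = result.inserted_seq
    else:
        remaining = max(
            1, gap.expected_len - len(result.left_ext) - len(result.right_ext)
        )
        replacement = result.left_ext + "N" * remaining + result.right_ext
    return Scaffold(scaffold.id, scaffold.seq[:s] + replacement + scaffold.seq[e:])
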