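"""Pipeline orchestration: global iterations, reporting, and the CLI.

One global iteration re-anchors all library reads against the current
assembly, recruits mates into gaps, fills every fillable gap and
rewrites the scaffolds.  Iterations repeat up to ``i`` times, stopping
early as soon as a round inserts nothing.  Gap-edge trimming is a
pre-filtering step applied in the first iteration only: later rounds
operate on edges the tool itself produced and re-vetted.

The run is deterministic: byte-identical outputs for identical inputs
and flags, independent of the thread-count hint.
"""

from __future__ import annotations

import argparse
import logging
import os
import sys
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .extension import apply_closure, fill_gap, trim_gap_edges
from .io_formats import (
    ReportRow,
    assembly_stats,
    n50,
    parse_library_file,
    read_fasta,
    read_pairs,
    write_fasta,
    write_gap_report,
)
from .model import (
    ClosureResult,
    GapRecord,
    GapStatus,
    Library,
    Parameters,
    Reason,
    Scaffold,
    find_gaps,
)
from .placement import build_index, recruit_from_sam, recruit_pairs

__all__ = ["run_iteration", "run", "RunResult", "IterationStats", "cli", "main"]

log = logging.getLogger("gapclose")


@dataclass
class IterationStats:
    iteration: int
    gaps_closed: int
    nucleotides_inserted: int
    gaps_remaining: int
    total_gap_length: int


@dataclass
class _TrackedGap:
    """Identity of one original input gap across iterations."""

    gid: int
    scaffold_id: str
    start: int  # original (pre-trim) interval on the input assembly
    end: int
    expected_len: int = 0
    terminal: bool = False
    closed: ClosureResult | None = None
    last_result: ClosureResult | None = None
    total_ext: int = 0
    # A size-vetoed merge is the most diagnostic failure for a gap that
    # never closes; remember it even if later rounds merely exhaust.
    size_vetoed: bool = False


@dataclass
class RunResult:
    scaffolds: list[Scaffold]
    rows: list[ReportRow]
    summary: dict[str, int]
    iterations: list[IterationStats]


def _recruit_all(
    scaffolds: list[Scaffold],
    records: list[GapRecord],
    libraries: Sequence[Library],
    params: Parameters,
):
    """Anchor every library's pairs and pool recruits per gap."""
    index = build_index(scaffolds, params.seed_len)
    scaffold_map = {sc.id: sc.seq for sc in scaffolds}
    recruited: dict[tuple[str, int, int], list[tuple[str, str]]] = defaultdict(list)
    for lib in libraries:
        if lib.sam_path is not None:
            recruit_from_sam(
                lib.sam_path, scaffold_map, records, lib, params, result=recruited
            )
        else:
            pairs = read_pairs(lib.files[0], lib.files[1])
            recruit_pairs(pairs, index, records, lib, params, result=recruited)
    # Order-normalize so results do not depend on library/worker order.
    return {key: sorted(lst) for key, lst in recruited.items()}


def _flanks(seq: str, rec: GapRecord, m: int) -> tuple[str, str]:
    left = seq[max(0, rec.start - m) : rec.start]
    right = seq[rec.end : rec.end + m]
    return left, right


def run_iteration(
    scaffolds: list[Scaffold],
    libraries: Sequence[Library],
    params: Parameters,
    records_by_scaffold: dict[str, list[GapRecord]],
) -> tuple[list[Scaffold], dict[tuple[str, int, int], ClosureResult], IterationStats]:
    """Run one align → recruit → fill → rewrite round.

    ``records_by_scaffold`` holds the current gap records (already
    trimmed if this is the first round).  Returns the rewritten
    assembly, the closure result per gap key, and the round's stats.
    """
    all_records = [r for recs in records_by_scaffold.values() for r in recs]
    fillable = [r for r in all_records if not r.terminal]
    results: dict[tuple[str, int, int], ClosureResult] = {}
    if not fillable:
        stats = IterationStats(0, 0, 0, len(all_records), sum(
            r.end - r.start for r in all_records
        ))
        return scaffolds, results, stats

    recruited = _recruit_all(scaffolds, fillable, libraries, params)

    closed = 0
    inserted = 0
    new_scaffolds: list[Scaffold] = []
    for sc in scaffolds:
        recs = records_by_scaffold.get(sc.id, [])
        cur = sc
        # Apply right-to-left so earlier coordinates stay valid.
        for rec in sorted(recs, key=lambda r: r.start, reverse=True):
            if rec.terminal:
                results[rec.key] = ClosureResult(
                    status=GapStatus.OPEN, reason=Reason.NO_READS
                )
                continue
            reads = [seq for _, seq in recruited.get(rec.key, [])]
            lf, rf = _flanks(cur.seq, rec, params.m)
            res = fill_gap(rec, reads, params, lf, rf)
            results[rec.key] = res
            if res.status is GapStatus.CLOSED:
                closed += 1
                inserted += len(res.inserted_seq)
            elif res.status is GapStatus.PARTIAL:
                inserted += len(res.left_ext) + len(res.right_ext)
            cur = apply_closure(cur, rec, res)
        new_scaffolds.append(cur)

    remaining = 0
    gap_len = 0
    for sc in new_scaffolds:
        for g in find_gaps(sc):
            remaining += 1
            gap_len += g.end - g.start
    stats = IterationStats(0, closed, inserted, remaining, gap_len)
    return new_scaffolds, results, stats


def run(
    scaffolds: Iterable[Scaffold],
    libraries: Sequence[Library],
    params: Parameters,
) -> RunResult:
    """Run up to ``params.i`` global iterations and build the report.

    Stops early once an iteration inserts zero nucleotides.  The
    report carries one row per original input gap with its final
    status; the summary block holds the before/after assembly metrics
    (scaffold count, gap count, total gap length, N50).
    """
    scaffolds = list(scaffolds)
    before = assembly_stats(scaffolds)

    tracked: list[_TrackedGap] = []
    # Per scaffold, the gids of still-open gaps in left-to-right order.
    open_order: dict[str, list[int]] = {}

    iterations: list[IterationStats] = []
    for it in range(params.i):
        records_by_scaffold: dict[str, list[GapRecord]] = {}
        if it == 0:
            new_scaffolds = []
            for sc in scaffolds:
                gaps = find_gaps(sc)
                trimmed, records = trim_gap_edges(sc, gaps, params.t)
                gids = []
                for gap, rec in zip(gaps, records):
                    gid = len(tracked)
                    tracked.append(
                        _TrackedGap(
                            gid=gid,
                            scaffold_id=sc.id,
                            start=gap.start,
                            end=gap.end,
                            expected_len=rec.expected_len,
                            terminal=rec.terminal,
                        )
                    )
                    gids.append(gid)
                open_order[sc.id] = gids
                records_by_scaffold[sc.id] = records
                new_scaffolds.append(trimmed)
            scaffolds = new_scaffolds
        else:
            for sc in scaffolds:
                runs = find_gaps(sc)
                gids = open_order[sc.id]
                if len(runs) != len(gids):  # pragma: no cover - invariant guard
                    raise RuntimeError(
                        f"{sc.id}: gap tracking lost ({len(runs)} N-runs, "
                        f"{len(gids)} tracked gaps)"
                    )
                records_by_scaffold[sc.id] = [
                    GapRecord(
                        scaffold_id=sc.id,
                        start=g.start,
                        end=g.end,
                        expected_len=g.end - g.start,
                        terminal=g.terminal or tracked[gid].terminal,
                    )
                    for g, gid in zip(runs, gids)
                ]

        if not any(
            not r.terminal
            for recs in records_by_scaffold.values()
            for r in recs
        ):
            break

        scaffolds, results, stats = run_iteration(
            scaffolds, libraries, params, records_by_scaffold
        )
        stats.iteration = it + 1
        iterations.append(stats)
        log.info(
            "iteration %d: closed=%d inserted=%d remaining=%d gap_length=%d",
            stats.iteration,
            stats.gaps_closed,
            stats.nucleotides_inserted,
            stats.gaps_remaining,
            stats.total_gap_length,
        )

        # Fold this round's outcomes into the per-original-gap ledger.
        for sid, recs in records_by_scaffold.items():
            gids = open_order[sid]
            still_open = []
            for rec, gid in zip(recs, gids):
                res = results.get(rec.key)
                tg = tracked[gid]
                if res is None:
                    still_open.append(gid)
                    continue
                tg.last_result = res
                if res.status is GapStatus.CLOSED:
                    tg.closed = res
                else:
                    if res.reason is Reason.SIZE_MISMATCH:
                        tg.size_vetoed = True
                    tg.total_ext += len(res.left_ext) + len(res.right_ext)
                    still_open.append(gid)
            open_order[sid] = still_open

        if stats.nucleotides_inserted == 0:
            break

    scaffolds = list(scaffolds)
    after = assembly_stats(scaffolds)

    # Remaining N-run lengths, mapped back to original gaps in order.
    remaining_n: dict[int, int] = {}
    for sc in scaffolds:
        runs = find_gaps(sc)
        gids = open_order.get(sc.id, [])
        for g, gid in zip(runs, gids):
            remaining_n[gid] = g.end - g.start

    rows: list[ReportRow] = []
    for tg in tracked:
        if tg.closed is not None:
            status = GapStatus.CLOSED
            filled = len(tg.closed.inserted_seq)
            remaining = 0
            overlap = tg.closed.overlap_len
            reason = Reason.OK
        else:
            status = GapStatus.PARTIAL if tg.total_ext > 0 else GapStatus.OPEN
            filled = tg.total_ext
            remaining = remaining_n.get(tg.gid, tg.end - tg.start)
            overlap = 0
            if tg.size_vetoed:
                reason = Reason.SIZE_MISMATCH
            elif tg.last_result is not None:
                reason = tg.last_result.reason
            else:
                reason = Reason.NO_READS
        rows.append(
            ReportRow(
                scaffold_id=tg.scaffold_id,
                start=tg.start,
                end=tg.end,
                expected_len=tg.expected_len,
                status=status,
                filled_len=filled,
                remaining_n=remaining,
                overlap_len=overlap,
                reason=reason.value,
            )
        )

    summary = {
        "scaffold_count": before["scaffold_count"],
        "gap_count_before": before["gap_count"],
        "gap_count_after": after["gap_count"],
        "total_gap_length_before": before["total_gap_length"],
        "total_gap_length_after": after["total_gap_length"],
        "n50_before": before["n50"],
        "n50_after": after["n50"],
        "total_length_before": before["total_length"],
        "total_length_after": after["total_length"],
    }
    return RunResult(scaffolds, rows, summary, iterations)


def _build_parser() -> argparse.ArgumentParser:
    p = argparse.ArgumentParser(
        prog="gapclose",
        description="Close intra-scaffold gaps (N-runs) using paired short reads.",
    )
    p.add_argument("-s", dest="scaffolds", required=True, help="scaffold FASTA")
    p.add_argument("-l", dest="libraries", required=True, help="library description file")
    p.add_argument("-m", dest="m", type=int, default=29, help="extension overlap length (k = m + 1)")
    p.add_argument("-o", dest="o", type=int, default=2, help="minimum overhang coverage")
    p.add_argument("-r", dest="r", type=float, default=0.7, help="majority voting ratio")
    p.add_argument("-n", dest="n", type=int, default=10, help="minimum merge overlap")
    p.add_argument("-d", dest="d", type=int, default=50, help="max insertion/expected length difference")
    p.add_argument("-t", dest="t", type=int, default=10, help="gap-edge trim length")
    p.add_argument("-i", dest="i", type=int, default=10, help="maximum global iterations")
    p.add_argument("-T", dest="threads", type=int, default=1, help="thread-count hint (results are independent of it)")
    p.add_argument("-b", dest="basename", default="gapclose", help="output basename")
    p.add_argument("--seed", dest="seed", type=int, default=0, help="seed for stochastic components")
    p.add_argument("--log", dest="log_level", default="INFO", help="logging level")
    return p


def cli(argv: Sequence[str] | None = None) -> int:
    """Command-line entry point; returns the process exit code."""
    parser = _build_parser()
    try:
        args = parser.parse_args(argv)
    except SystemExit as exc:
        return int(exc.code or 0)

    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, str(args.log_level).upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
    )

    outputs = [
        f"{args.basename}.gapfilled.fasta",
        f"{args.basename}.gaps.tsv",
        f"{args.basename}.summary.txt",
    ]
    try:
        params = Parameters(
            t=args.t,
            m=args.m,
            o=args.o,
            r=args.r,
            n=args.n,
            d=args.d,
            i=args.i,
            rng_seed=args.seed,
            threads=args.threads,
        )
    except ValueError as exc:
        print(f"gapclose: invalid parameters: {exc}", file=sys.stderr)
        return 2

    try:
        scaffolds = [Scaffold(rid, seq) for rid, seq in read_fasta(args.scaffolds)]
        libraries = parse_library_file(args.libraries)
        log.info(
            "parameters: t=%d m=%d k=%d o=%d r=%g n=%d d=%d i=%d",
            params.t, params.m, params.k, params.o, params.r,
            params.n, params.d, params.i,
        )
        result = run(scaffolds, libraries, params)
        write_fasta(((sc.id, sc.seq) for sc in result.scaffolds), outputs[0])
        write_gap_report(result.rows, result.summary, outputs[1])
        with open(outputs[2], "w") as fh:
            for key, value in result.summary.items():
                fh.write(f"{key}\t{value}\n")
    except (OSError, ValueError, RuntimeError) as exc:
        for out in outputs:
            if os.path.exists(out):
                os.unlink(out)
        print(f"gapclose: error: {exc}", file=sys.stderr)
        return 1
    return 0


def main() -> None:  # pragma: no cover - console entry point
    sys.exit(cli())
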