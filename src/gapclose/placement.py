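"""Read anchoring and gap recruitment.

One mate of each pair is anchored to scaffold sequence; the other mate
is recruited to every gap its predicted position (from the library's
insert-size model) overlaps.  Anchoring uses a deterministic
seed-and-verify mapper: exact seed lookup on both strands followed by
full-length verification with a bounded mismatch count and no indels.
Only uniquely best placements are kept — multi-mapping anchors would
recruit reads from repeat copies, the dominant error source in gap
closing.  Externally computed SAM placements can be ingested instead.
"""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Iterable, Iterator

import pysam

from .model import (
    GapRecord,
    Library,
    Parameters,
    Placement,
    Scaffold,
    revcomp,
)
from .io_formats import ReadPair, _strip_mate_decoration

__all__ = [
    "ScaffoldIndex",
    "build_index",
    "place_read",
    "mate_window",
    "recruit_pairs",
    "recruit_from_sam",
    "GapKey",
]

GapKey = tuple[str, int, int]


class ScaffoldIndex:
    """Exact-seed lookup table over the forward strands of all scaffolds.

    Maps every N-free ``seed_len`` window to its (scaffold id,
    position) occurrences.
    """

    __slots__ = ("seed_len", "scaffolds", "seeds")

    def __init__(self, scaffolds: dict[str, str], seed_len: int):
        if seed_len < 1:
            raise ValueError("seed_len must be >= 1")
        self.seed_len = seed_len
        self.scaffolds = scaffolds
        self.seeds: dict[str, list[tuple[str, int]]] = {}
        for sid, seq in scaffolds.items():
            self._index_one(sid, seq)

    def _index_one(self, sid: str, seq: str) -> None:
        L = self.seed_len
        seeds = self.seeds
        # Skip windows overlapping N by jumping past each N position.
        pos = 0
        limit = len(seq) - L + 1
        while pos < limit:
            window = seq[pos : pos + L]
            n_at = window.rfind("N")
            if n_at >= 0:
                pos += n_at + 1
                continue
            seeds.setdefault(window, []).append((sid, pos))
            pos += 1


def build_index(scaffolds: Iterable[Scaffold], seed_len: int) -> ScaffoldIndex:
    """Index all N-free seed windows of every scaffold."""
    return ScaffoldIndex({sc.id: sc.seq for sc in scaffolds}, seed_len)


def _count_mismatches(a: str, b: str, budget: int) -> int:
    """Mismatches between equal-length strings, or budget + 1 if exceeded."""
    if a == b:
        return 0
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > budget:
                return mm
    return mm


def place_read(
    read_seq: str,
    index: ScaffoldIndex,
    params: Parameters,
    read_id: str = "",
) -> Placement | None:
    """Anchor a read by seed lookup plus full-length verification.

    Candidate loci come from the read's first ``seed_len`` bases on the
    forward read and on its reverse complement; each is verified
    allowing at most ``floor(max_mismatch_frac * read_length)``
    mismatches and no indels.  Returns the unique best-scoring
    placement, or None for zero candidates, a best-score tie across
    distinct loci, or a read shorter than the seed.
    """
    L = len(read_seq)
    if L < index.seed_len:
        return None
    budget = int(params.max_mismatch_frac * L)
    candidates: dict[tuple[str, int, str], int] = {}

    def _verify(query: str, strand: str) -> None:
        hits = index.seeds.get(query[: index.seed_len])
        if not hits:
            return
        for sid, pos in hits:
            seq = index.scaffolds[sid]
            if pos + L > len(seq):
                continue
            mm = _count_mismatches(query, seq[pos : pos + L], budget)
            if mm <= budget:
                key = (sid, pos, strand)
                prev = candidates.get(key)
                if prev is None or mm < prev:
                    candidates[key] = mm

    _verify(read_seq, "+")
    _verify(revcomp(read_seq), "-")

    if not candidates:
        return None
    best_mm = min(candidates.values())
    best = [key for key, mm in candidates.items() if mm == best_mm]
    if len(best) != 1:
        return None
    sid, pos, strand = best[0]
    return Placement(
        read_id=read_id,
        scaffold_id=sid,
        start=pos,
        strand=strand,
        mismatches=best_mm,
    )


def mate_window(
    placement: Placement,
    lib: Library,
    anchor_len: int,
    mate_len: int,
    scaffold_len: int,
) -> tuple[int, int]:
    """Predicted interval of the mate's footprint on the scaffold.

    The insert size spans the 5' end of read 1 to the 5' end of read 2
    (outer distance); the library deviation widens it symmetrically.
    For a forward anchor starting at ``s`` the mate may start anywhere
    in ``[s + (1-v)I - mate_len, s + (1+v)I)``; a reverse anchor with
    5' end at ``e = s + anchor_len`` mirrors this upstream.  The window
    is clipped to the scaffold; an empty window discards the pair.
    """
    ins = lib.insert_size
    v = lib.deviation
    if placement.strand == "+":
        lo = math.floor(placement.start + (1 - v) * ins) - mate_len
        hi = math.ceil(placement.start + (1 + v) * ins)
    else:
        e = placement.start + anchor_len
        lo = math.floor(e - (1 + v) * ins)
        hi = math.ceil(e - (1 - v) * ins) + mate_len
    return (max(0, lo), min(hi, scaffold_len))


def _gaps_by_scaffold(
    gaps: Iterable[GapRecord],
) -> dict[str, list[tuple[GapKey, int, int]]]:
    out: dict[str, list[tuple[GapKey, int, int]]] = defaultdict(list)
    for gap in gaps:
        if gap.terminal:
            continue
        out[gap.scaffold_id].append((gap.key, gap.start, gap.end))
    return out


def _recruit_one(
    anchor_seq: str,
    recruit_seq: str,
    pair_id: str,
    index: ScaffoldIndex,
    gap_map: dict[str, list[tuple[GapKey, int, int]]],
    lib: Library,
    params: Parameters,
    result: dict[GapKey, list[tuple[str, str]]],
) -> bool:
    pl = place_read(anchor_seq, index, params, read_id=pair_id)
    if pl is None:
        return False
    gaps_here = gap_map.get(pl.scaffold_id)
    if gaps_here:
        lo, hi = mate_window(
            pl, lib, len(anchor_seq), len(recruit_seq), len(index.scaffolds[pl.scaffold_id])
        )
        if lo < hi:
            for key, gs, ge in gaps_here:
                if max(lo, gs) < min(hi, ge):
                    result[key].append((pair_id, recruit_seq))
    return True


def recruit_pairs(
    pairs: Iterable[ReadPair],
    index: ScaffoldIndex,
    gaps: Iterable[GapRecord],
    lib: Library,
    params: Parameters,
    result: dict[GapKey, list[tuple[str, str]]] | None = None,
) -> dict[GapKey, list[tuple[str, str]]]:
    """Recruit the unanchored mate of each pair to every gap its window hits.

    Mate 1 is anchored first; if it is unplaceable, mate 2 is tried and
    mate 1 becomes the recruit.  RF (mate-pair) libraries are
    normalized to FR by reverse complementing both mates on input.  A
    pair whose anchored mate's window intersects no gap contributes
    nothing.  Recruit lists are sorted by read id at the end so the
    outcome is independent of pair order.
    """
    if result is None:
        result = defaultdict(list)
    elif not isinstance(result, defaultdict):
        tmp: dict[GapKey, list[tuple[str, str]]] = defaultdict(list)
        tmp.update(result)
        result = tmp
    gap_map = _gaps_by_scaffold(gaps)
    for pair in pairs:
        s1, s2 = pair.seq1, pair.seq2
        if lib.orientation == "RF":
            s1, s2 = revcomp(s1), revcomp(s2)
        if not _recruit_one(s1, s2, pair.id, index, gap_map, lib, params, result):
            _recruit_one(s2, s1, pair.id, index, gap_map, lib, params, result)
    for lst in result.values():
        lst.sort()
    return dict(result)


def recruit_from_sam(
    sam_path: str,
    scaffolds: dict[str, str],
    gaps: Iterable[GapRecord],
    lib: Library,
    params: Parameters,
    result: dict[GapKey, list[tuple[str, str]]] | None = None,
) -> dict[GapKey, list[tuple[str, str]]]:
    """Recruit mates using placements from an external aligner's SAM.

    Primary records are grouped per read pair; the first mapped mate
    acts as the anchor and the other mate's stored sequence is the
    recruit.  Window logic matches the built-in mapper.
    """
    if result is None:
        result = defaultdict(list)
    gap_map = _gaps_by_scaffold(gaps)

    mates: dict[str, dict[int, tuple[Placement | None, str, int]]] = defaultdict(dict)
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        for ref in sam.references:
            if ref not in scaffolds:
                raise ValueError(
                    f"{sam_path}: @SQ reference {ref!r} is not an input scaffold"
                )
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            seq = rec.query_sequence or ""
            # SAM stores mapped reverse-strand reads as the reference
            # strand sequence; irrelevant downstream (k-merization is
            # strand closed), so the sequence is taken as stored.
            mate_no = 2 if rec.is_read2 else 1
            if rec.is_unmapped:
                pl = None
            else:
                pl = Placement(
                    read_id=_strip_mate_decoration(rec.query_name),
                    scaffold_id=rec.reference_name,
                    start=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    mismatches=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                )
            mates[_strip_mate_decoration(rec.query_name)][mate_no] = (
                pl,
                seq,
                rec.query_length or len(seq),
            )

    for rid in sorted(mates):
        recs = mates[rid]
        if 1 not in recs or 2 not in recs:
            continue
        pl1, seq1, len1 = recs[1]
        pl2, seq2, len2 = recs[2]
        if pl1 is not None:
            anchor, anchor_len, recruit = pl1, len1, seq2
        elif pl2 is not None:
            anchor, anchor_len, recruit = pl2, len2, seq1
        else:
            continue
        if not recruit:
            continue
        gaps_here = gap_map.get(anchor.scaffold_id)
        if not gaps_here:
            continue
        lo, hi = mate_window(
            anchor, lib, anchor_len, len(recruit), len(scaffolds[anchor.scaffold_id])
        )
        if lo >= hi:
            continue
        for key, gs, ge in gaps_here:
            if max(lo, gs) < min(hi, ge):
                result[key].append((rid, recruit))
    for lst in result.values():
        lst.sort()
    return dict(result)
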