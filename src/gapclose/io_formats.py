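"""Readers and writers for the pipeline's on-disk formats.

FASTA scaffolds in and out (60-column wrap on output), FASTQ/FASTA
paired-read files, an optional plain-text SAM ingestion path for
externally computed read placements, the library description file, and
the per-gap TSV report with its assembly summary block.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Iterator

import pysam
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .model import (
    ClosureResult,
    GapStatus,
    Library,
    Placement,
    Scaffold,
    normalize_sequence,
)

__all__ = [
    "ReadPair",
    "read_fasta",
    "write_fasta",
    "read_pairs",
    "parse_library_file",
    "read_sam_placements",
    "ReportRow",
    "write_gap_report",
    "n50",
    "assembly_stats",
]


@dataclass
class ReadPair:
    """Two mates of one sequenced fragment, plus optional qualities.

    Base qualities are carried through for provenance but never used by
    the closing algorithm.
    """

    id: str
    seq1: str
    seq2: str
    qual1: str | None = None
    qual2: str | None = None


def read_fasta(path: str) -> Iterator[tuple[str, str]]:
    """Stream (id, normalized sequence) records from a FASTA file.

    Raises on an empty file or an empty record sequence.
    """
    count = 0
    for rec in SeqIO.parse(path, "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        count += 1
        yield rec.id, normalize_sequence(seq, rec.id)
    if count == 0:
        raise ValueError(f"{path}: no FASTA records found")


def write_fasta(records: Iterable[tuple[str, str]], path: str, width: int = 60) -> None:
    """Write (id, seq) records as FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for j in range(0, len(seq), width):
                fh.write(seq[j : j + width])
                fh.write("\n")


def _strip_mate_decoration(title: str) -> str:
    # Casava 1.8 puts the mate flag after a space ("... 1:N:0:..."),
    # older dialects append /1 or /2 to the id itself.
    rid = title.split()[0]
    if rid.endswith("/1") or rid.endswith("/2"):
        rid = rid[:-2]
    return rid


def _iter_reads(path: str) -> Iterator[tuple[str, str, str | None]]:
    """Yield (id, seq, qual) from a FASTQ or FASTA file, auto-detected."""
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        with open(path) as fh:
            for title, seq, qual in FastqGeneralIterator(fh):
                yield _strip_mate_decoration(title), seq, qual
    elif first == ">":
        for rec in SeqIO.parse(path, "fasta"):
            yield _strip_mate_decoration(rec.description or rec.id), str(rec.seq), None
    else:
        raise ValueError(f"{path}: not FASTA or FASTQ (first character {first!r})")


def read_pairs(file_a: str, file_b: str) -> Iterator[ReadPair]:
    """Iterate mates of two position-matched read files as ReadPairs.

    The files must contain the same number of records in the same
    order; a count mismatch raises at the first divergence, as does a
    mate-id disagreement after stripping /1, /2 or Casava decorations.
    """
    _MISSING = object()
    it_a = _iter_reads(file_a)
    it_b = _iter_reads(file_b)
    from itertools import zip_longest

    for rec_a, rec_b in zip_longest(it_a, it_b, fillvalue=_MISSING):
        if rec_a is _MISSING or rec_b is _MISSING:
            short = file_a if rec_a is _MISSING else file_b
            raise ValueError(f"{short}: fewer records than its mate file")
        id_a, seq_a, qual_a = rec_a
        id_b, seq_b, qual_b = rec_b
        if id_a != id_b:
            raise ValueError(
                f"mate id mismatch: {id_a!r} ({file_a}) vs {id_b!r} ({file_b})"
            )
        if not seq_a or not seq_b:
            raise ValueError(f"pair {id_a!r}: empty mate sequence")
        yield ReadPair(
            id=id_a,
            seq1=normalize_sequence(seq_a, id_a),
            seq2=normalize_sequence(seq_b, id_a),
            qual1=qual_a,
            qual2=qual_b,
        )


def parse_library_file(path: str, base_dir: str | None = None) -> list[Library]:
    """Parse the library description file.

    One library per line, whitespace separated::

        name fileA fileB insert_size deviation orientation

    ``#`` starts a comment.  External SAM placements are selected by
    giving ``sam:<path>`` as fileA and ``-`` as fileB.  Relative read
    file paths are resolved against ``base_dir`` (default: the library
    file's directory).
    """
    if base_dir is None:
        base_dir = os.path.dirname(os.path.abspath(path))
    libs: list[Library] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            cols = line.split()
            if len(cols) != 6:
                raise ValueError(
                    f"{path}:{lineno}: expected 6 columns "
                    f"(name fileA fileB insert deviation orientation), got {len(cols)}"
                )
            name, fa, fb, ins, dev, orient = cols
            try:
                insert_size = float(ins)
                deviation = float(dev)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: insert size and deviation must be numeric"
                ) from None

            def _resolve(p: str) -> str:
                if p == "-" or os.path.isabs(p):
                    return p
                if p.startswith("sam:"):
                    return "sam:" + _resolve(p[4:])
                return os.path.join(base_dir, p)

            try:
                lib = Library(
                    name=name,
                    files=(_resolve(fa), _resolve(fb)),
                    insert_size=insert_size,
                    deviation=deviation,
                    orientation=orient,
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            libs.append(lib)
    return libs


def read_sam_placements(
    path: str, scaffolds: dict[str, str]
) -> Iterator[tuple[str, Placement]]:
    """Yield (read id, Placement) for mapped primary SAM records.

    Unmapped, secondary (0x100) and supplementary (0x800) records are
    skipped.  SAM's 1-based POS is converted to a 0-based start and
    FLAG bit 0x10 becomes strand '-'.  Every @SQ reference must be a
    known scaffold id.
    """
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for ref in sam.references:
            if ref not in scaffolds:
                raise ValueError(
                    f"{path}: @SQ reference {ref!r} is not an input scaffold"
                )
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            yield (
                _strip_mate_decoration(rec.query_name),
                Placement(
                    read_id=_strip_mate_decoration(rec.query_name),
                    scaffold_id=rec.reference_name,
                    start=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    mismatches=int(nm),
                ),
            )


def n50(lengths: Iterable[int]) -> int:
    """N50 of a set of sequence lengths (0 for an empty/zero set)."""
    lengths = sorted(lengths, reverse=True)
    total = sum(lengths)
    if total == 0:
        return 0
    acc = 0
    for length in lengths:
        acc += length
        if 2 * acc >= total:
            return length
    return 0  # pragma: no cover


def assembly_stats(scaffolds: Iterable[Scaffold]) -> dict[str, int]:
    """Scaffold count, gap count, total gap length and N50 of an assembly."""
    from .model import find_gaps

    scaffolds = list(scaffolds)
    gap_count = 0
    gap_len = 0
    for sc in scaffolds:
        for g in find_gaps(sc):
            gap_count += 1
            gap_len += g.end - g.start
    return {
        "scaffold_count": len(scaffolds),
        "gap_count": gap_count,
        "total_gap_length": gap_len,
        "n50": n50(len(sc.seq) for sc in scaffolds),
        "total_length": sum(len(sc.seq) for sc in scaffolds),
    }


@dataclass
class ReportRow:
    """One original gap's final outcome for the TSV report."""

    scaffold_id: str
    start: int
    end: int
    expected_len: int
    status: GapStatus
    filled_len: int
    remaining_n: int
    overlap_len: int
    reason: str


_REPORT_COLUMNS = [
    "scaffold_id",
    "gap_start",
    "gap_end",
    "expected_len",
    "status",
    "filled_len",
    "remaining_n",
    "overlap_len",
    "reason",
]


def write_gap_report(
    rows: Iterable[ReportRow], summary: dict[str, int], path: str
) -> None:
    """Write the per-gap TSV report followed by a commented summary block."""
    with open(path, "w") as fh:
        fh.write("\t".join(_REPORT_COLUMNS) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        row.scaffold_id,
                        row.start,
                        row.end,
                        row.expected_len,
                        row.status.value,
                        row.filled_len,
                        row.remaining_n,
                        row.overlap_len,
                        row.reason,
                    )
                )
                + "\n"
            )
        for key, value in summary.items():
            fh.write(f"# {key}\t{value}\n")
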