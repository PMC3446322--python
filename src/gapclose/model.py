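"""Core domain types for scaffold gap closing.

A draft genome assembly is usually delivered as *scaffolds*: contigs
ordered and oriented by paired-read linkage, joined by runs of ``N``
whose length is the scaffolder's estimate of the missing sequence.
Everything in this package operates on that representation.  The types
here are shared by every stage of the pipeline: the parameter set, the
scaffold and gap records, read libraries, read placements, the k-mer
multiset used for edge extension, and the per-gap closure outcome.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "revcomp",
    "normalize_sequence",
    "find_gaps",
    "GapInterval",
    "Parameters",
    "Scaffold",
    "GapStatus",
    "Reason",
    "GapRecord",
    "Library",
    "Placement",
    "KmerStore",
    "ClosureResult",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A, C, G, T, N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


# Case-folding plus IUPAC handling: A/C/G/T survive, every other IUPAC
# nucleotide symbol (ambiguity codes, U) and the gap characters '-'/'.'
# collapse to N.  Ambiguous bases cannot seed deterministic k-mer
# extension, so they are treated as unknown sequence.
_NORM_MAP: dict[str, str] = {}
for _c in "ACGT":
    _NORM_MAP[_c] = _c
    _NORM_MAP[_c.lower()] = _c
for _c in "NURYSWKMBDHV-.":
    _NORM_MAP[_c] = "N"
    _NORM_MAP[_c.lower()] = "N"
_NORM_TABLE = str.maketrans(_NORM_MAP)
_ALLOWED = frozenset("ACGTN")

_N_RUN = re.compile("N+")


def normalize_sequence(raw: str, record_id: str = "?") -> str:
    """Normalize a raw FASTA sequence to the {A,C,G,T,N} alphabet.

    Uppercases, maps IUPAC ambiguity codes (and U, '-', '.') to N and
    rejects anything that is not an IUPAC nucleotide symbol.

    Raises
    ------
    ValueError
        If the sequence contains a character outside the IUPAC
        nucleotide alphabet; the message names the record and the
        offending character.
    """
    out = raw.translate(_NORM_TABLE)
    bad = set(out) - _ALLOWED
    if bad:
        ch = sorted(bad)[0]
        raise ValueError(
            f"record {record_id!r}: invalid sequence character {ch!r}"
        )
    return out


@dataclass(frozen=True)
class GapInterval:
    """A maximal N-run, half-open [start, end).

    ``terminal`` marks runs touching a scaffold boundary; those have a
    single flank and can never be filled.
    """

    start: int
    end: int
    terminal: bool = False


def find_gaps(scaffold: "Scaffold") -> list[GapInterval]:
    """Locate all maximal N-runs of a normalized scaffold, left to right."""
    seq = scaffold.seq
    out = []
    for m in _N_RUN.finditer(seq):
        s, e = m.span()
        out.append(GapInterval(s, e, terminal=(s == 0 or e == len(seq))))
    return out


@dataclass
class Parameters:
    """Tuning knobs shared by every pipeline stage.

    Attributes
    ----------
    t : int
        Gap-edge trim length in nucleotides.  Contig ends bordering a
        gap frequently carry misassembled bases, so each gap is first
        enlarged by up to ``t`` flanking bases per side.
    m : int
        Extension overlap length; the k-mer size is ``k = m + 1`` (one
        overhang base beyond an m-long edge overlap).
    o : int
        Minimum count of k-mers supporting the winning overhang base.
    r : float
        Majority voting ratio in [0.5, 1]: the winning base must carry
        at least this fraction of all overhang support (0.5 is the
        documented low-coverage setting).
    n : int
        Minimum suffix/prefix overlap (nt) required to merge the left
        and right extensions.
    d : int
        Maximum allowed difference (nt) between the inserted sequence
        length and the expected gap length.
    i : int
        Maximum number of global iterations (align, recruit, fill).
    seed_len : int
        Seed length of the built-in read anchorer.
    max_mismatch_frac : float
        Mismatch budget for full-read anchor verification, as a
        fraction of read length.
    rng_seed : int
        Seed for any stochastic component (the simulator; the closing
        algorithm itself is deterministic).
    threads : int
        Worker count hint.  Results are required to be independent of
        this value; the current implementation is serial.
    """

    t: int = 10
    m: int = 29
    o: int = 2
    r: float = 0.7
    n: int = 10
    d: int = 50
    i: int = 10
    seed_len: int = 30
    max_mismatch_frac: float = 0.04
    rng_seed: int = 0
    threads: int = 1

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("t must be >= 0")
        if self.m < 1:
            raise ValueError("m must be >= 1 (so that k = m + 1 >= 2)")
        if self.o < 1:
            raise ValueError("o must be >= 1")
        # r = 0.5 is meaningful (the documented low-coverage mode);
        # exact ties still halt extension via the uniqueness rule.
        if not (0.5 <= self.r <= 1.0):
            raise ValueError("r must lie in [0.5, 1]")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.d < 0:
            raise ValueError("d must be >= 0")
        if self.i < 1:
            raise ValueError("i must be >= 1")
        if self.seed_len < 1:
            raise ValueError("seed_len must be >= 1")
        if not (0.0 <= self.max_mismatch_frac < 1.0):
            raise ValueError("max_mismatch_frac must lie in [0, 1)")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")

    @property
    def k(self) -> int:
        """k-mer size; always m + 1."""
        return self.m + 1


@dataclass
class Scaffold:
    """A named nucleotide sequence over {A,C,G,T,N}, uppercase."""

    id: str
    seq: str


class GapStatus(str, Enum):
    OPEN = "OPEN"
    CLOSED = "CLOSED"
    PARTIAL = "PARTIAL"


class Reason(str, Enum):
    OK = "OK"
    NO_OVERLAP = "NO_OVERLAP"
    SIZE_MISMATCH = "SIZE_MISMATCH"
    NO_COVERAGE = "NO_COVERAGE"
    AMBIGUOUS = "AMBIGUOUS"
    NO_READS = "NO_READS"


@dataclass
class GapRecord:
    """One gap's coordinates and fill state on its scaffold.

    ``expected_len`` is the target insertion length: the original
    N-count plus the flank bases actually trimmed into the gap.
    """

    scaffold_id: str
    start: int
    end: int
    expected_len: int
    left_ext: str = ""
    right_ext: str = ""
    status: GapStatus = GapStatus.OPEN
    terminal: bool = False

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.scaffold_id, self.start, self.end)


@dataclass
class Library:
    """A paired-read set with its insert-size model.

    ``orientation`` is FR for paired-end (mates face inward) or RF for
    mate-pair (outward) libraries.  ``files`` holds the two read file
    paths; in external-placement mode the first entry is ``sam:<path>``
    and the second ``-``.
    """

    name: str
    files: tuple[str, str]
    insert_size: float
    deviation: float
    orientation: str

    def __post_init__(self) -> None:
        if self.insert_size <= 0:
            raise ValueError(f"library {self.name}: insert_size must be > 0")
        if not (0.0 <= self.deviation < 1.0):
            raise ValueError(f"library {self.name}: deviation must lie in [0, 1)")
        if self.orientation not in ("FR", "RF"):
            raise ValueError(
                f"library {self.name}: orientation must be FR or RF, "
                f"got {self.orientation!r}"
            )

    @property
    def sam_path(self) -> str | None:
        """Path of the external SAM placement file, or None for read files."""
        if self.files[0].startswith("sam:"):
            return self.files[0][4:]
        return None


@dataclass(frozen=True)
class Placement:
    """A verified location of one read on the forward scaffold strand.

    ``start`` is the 0-based position of the read's leftmost base on
    the forward strand regardless of strand.
    """

    read_id: str
    scaffold_id: str
    start: int
    strand: str  # '+' or '-'
    mismatches: int


class KmerStore:
    """A multiset of k-mers recruited for one gap.

    Reads are added on both strands so extension is strand symmetric.
    Windows containing N contribute nothing.  ``remove_all`` implements
    removal-on-use: once an overhang base is incorporated, every copy
    of the k-mer that supported it is deleted.
    """

    __slots__ = ("k", "counts")

    def __init__(self, k: int):
        if k < 2:
            raise ValueError("k must be >= 2")
        self.k = k
        self.counts: dict[str, int] = {}

    def add_read(self, seq: str) -> None:
        """Add every N-free k-window of ``seq`` and of its reverse complement."""
        k = self.k
        counts = self.counts
        for s in (seq, revcomp(seq)):
            if len(s) < k:
                continue
            if "N" in s:
                for j in range(len(s) - k + 1):
                    w = s[j : j + k]
                    if "N" not in w:
                        counts[w] = counts.get(w, 0) + 1
            else:
                for j in range(len(s) - k + 1):
                    w = s[j : j + k]
                    counts[w] = counts.get(w, 0) + 1

    def count(self, kmer: str) -> int:
        return self.counts.get(kmer, 0)

    def remove_all(self, kmer: str) -> int:
        """Delete every copy of ``kmer``; return the multiplicity removed."""
        return self.counts.pop(kmer, 0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)

    def __bool__(self) -> bool:
        return bool(self.counts)


@dataclass
class ClosureResult:
    """Outcome of attempting to fill one gap.

    For CLOSED results ``inserted_seq`` replaces the (enlarged) N-run
    and ``overlap_len`` is the suffix/prefix overlap used to merge the
    two extensions.  For PARTIAL results the extensions are kept and
    the unresolved middle remains N.
    """

    status: GapStatus
    reason: Reason = Reason.OK
    inserted_seq: str = ""
    overlap_len: int = 0
    left_ext: str = ""
    right_ext: str = ""
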