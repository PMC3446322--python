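"""Canonical synthetic benchmark scenarios.

Each builder assembles a complete, truth-tracked test case — reference
genome, gapped scaffolds, and a simulated paired-end library on disk —
at the package's standard study conditions: a 2 x 70 bp FR library
with a 300 +/- 30 bp insert and 25% allowed deviation, gap sizes
within the reach of one insert.  The builders are deterministic given
a seed and are used both by the test suite and the reproduction
script.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

from .model import Library, Scaffold
from .simulate import (
    TruthRegistry,
    make_gapped_scaffolds,
    simulate_genome,
    simulate_read_pairs,
)

__all__ = [
    "Scenario",
    "perfect_recovery_scenario",
    "size_perturbed_scenario",
    "repeat_gap_scenario",
    "low_coverage_scenario",
]

READ_LEN = 70
INSERT_MEAN = 300
INSERT_SD = 30
DEVIATION = 0.25

# gap sizes spanning well below to near the insert reach
_GAP_LENGTHS = (20, 35, 50, 75, 100, 130, 160, 190, 220, 250)


@dataclass
class Scenario:
    genome: str
    scaffolds: list[Scaffold]
    registry: TruthRegistry
    library: Library


def _library(genome: str, workdir: str, seed: int, coverage: float,
             error_rate: float, tag: str) -> Library:
    r1 = os.path.join(workdir, f"{tag}_1.fq")
    r2 = os.path.join(workdir, f"{tag}_2.fq")
    simulate_read_pairs(
        genome, coverage, READ_LEN, INSERT_MEAN, INSERT_SD,
        error_rate, "FR", seed, r1, r2,
    )
    return Library(tag, (r1, r2), INSERT_MEAN, DEVIATION, "FR")


def perfect_recovery_scenario(
    workdir: str,
    seed: int = 0,
    coverage: float = 40.0,
    error_rate: float = 0.0,
    genome_len: int = 100_000,
    n_gaps: int = 20,
) -> Scenario:
    """Non-repetitive genome with 20 gaps of 20-250 bp at 40x coverage."""
    genome = simulate_genome(genome_len, rng_seed=seed * 1000 + 1)
    spacing = (genome_len - 6_000) // n_gaps
    specs = [
        (3_000 + j * spacing, _GAP_LENGTHS[j % len(_GAP_LENGTHS)])
        for j in range(n_gaps)
    ]
    scaffolds, registry = make_gapped_scaffolds(genome, specs)
    lib = _library(genome, workdir, seed * 1000 + 2, coverage, error_rate, "pr")
    return Scenario(genome, scaffolds, registry, lib)


def size_perturbed_scenario(
    workdir: str,
    seed: int = 0,
    n_gaps: int = 50,
    offset: int = 60,
    coverage: float = 40.0,
) -> Scenario:
    """Gaps whose N-run misstates the true size by ``offset`` bases.

    Emulates a scaffolder's wrong gap-size estimate: the emitted N-run
    is ``offset`` bases longer than the true missing sequence, so a
    correct reconstruction must be rejected by the size constraint
    whenever ``offset`` exceeds the tolerance ``d``.
    """
    genome_len = 2_000 + 2_300 * n_gaps + 2_000
    genome = simulate_genome(genome_len, rng_seed=seed * 1000 + 11)
    lengths = (30, 40, 50, 60)
    specs = [
        (2_000 + j * 2_300, lengths[j % len(lengths)], offset)
        for j in range(n_gaps)
    ]
    scaffolds, registry = make_gapped_scaffolds(genome, specs)
    lib = _library(genome, workdir, seed * 1000 + 12, coverage, 0.0, "sp")
    return Scenario(genome, scaffolds, registry, lib)


def repeat_gap_scenario(workdir: str, seed: int = 0, coverage: float = 40.0) -> Scenario:
    """One gap whose content carries two copies of a distal repeat.

    The gap content is REP + unique + REP where REP (40 bp, longer
    than k) is an exact copy of another genome locus.  Reads recruited
    to the gap support two different continuations at each repeat
    boundary with near-equal coverage, the classic unresolvable-repeat
    situation: extension must stall on ambiguity (or any collapsed
    merge must be vetoed by the size constraint), never emit a wrong
    closure.
    """
    genome = simulate_genome(30_000, rng_seed=seed * 1000 + 21)
    rep = genome[5_000:5_040]
    # unique filler, longer than d, generated apart from the genome
    mid = list(simulate_genome(70, rng_seed=seed * 1000 + 25))
    # force divergent continuations at both repeat boundaries
    if mid[0] == genome[15_150]:
        mid[0] = next(b for b in "ACGT" if b != genome[15_150])
    if mid[-1] == genome[14_999]:
        mid[-1] = next(b for b in "ACGT" if b != genome[14_999])
    content = rep + "".join(mid) + rep
    genome = genome[:15_000] + content + genome[15_150:]
    scaffolds, registry = make_gapped_scaffolds(genome, [(15_000, 150)])
    lib = _library(genome, workdir, seed * 1000 + 22, coverage, 0.0, "rg")
    return Scenario(genome, scaffolds, registry, lib)


def low_coverage_scenario(
    workdir: str, seed: int = 0, coverage: float = 10.0
) -> Scenario:
    """Eight gaps at 10x coverage, for threshold-sensitivity comparisons."""
    genome = simulate_genome(30_000, rng_seed=seed * 1000 + 31)
    specs = [
        (3_000 + j * 3_200, _GAP_LENGTHS[(2 * j) % len(_GAP_LENGTHS)])
        for j in range(8)
    ]
    scaffolds, registry = make_gapped_scaffolds(genome, specs)
    lib = _library(genome, workdir, seed * 1000 + 32, coverage, 0.0, "lc")
    return Scenario(genome, scaffolds, registry, lib)
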