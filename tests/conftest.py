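"""Shared fixtures: tiny deterministic simulations used across modules."""

import pytest

from gapclose.model import Library, Parameters
from gapclose.simulate import (
    make_gapped_scaffolds,
    simulate_genome,
    simulate_read_pairs,
)


@pytest.fixture()
def params():
    return Parameters()


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A 20 kb genome with 3 masked gaps and an error-free 30x FR library."""
    d = tmp_path_factory.mktemp("small_sim")
    genome = simulate_genome(20_000, rng_seed=11)
    scaffolds, registry = make_gapped_scaffolds(
        genome, [(4000, 30), (9000, 80), (14000, 150)]
    )
    r1 = str(d / "r1.fq")
    r2 = str(d / "r2.fq")
    simulate_read_pairs(genome, 30, 70, 300, 30, 0.0, "FR", 101, r1, r2)
    lib = Library("lib1", (r1, r2), 300, 0.25, "FR")
    return {
        "genome": genome,
        "scaffolds": scaffolds,
        "registry": registry,
        "library": lib,
        "reads": (r1, r2),
    }
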