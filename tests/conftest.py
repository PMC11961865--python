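"""Shared fixtures: toy construct/genome, scenarios and junction-read builders."""

from __future__ import annotations

import pytest

from tislocate.align import build_index, align_pair
from tislocate.calling import call_sample
from tislocate.construct import build_merged_reference, revcomp
from tislocate.simulate import (
    make_scenario,
    random_construct,
    simulate_genome,
    simulate_capture_library,
)


@pytest.fixture(scope="session")
def toy_construct():
    return random_construct(seed=5)


@pytest.fixture(scope="session")
def toy_genome():
    return simulate_genome(1, [10_000], gc=0.4, seed=11)


@pytest.fixture(scope="session")
def toy_merged(toy_genome, toy_construct):
    return build_merged_reference(toy_genome, toy_construct)


@pytest.fixture(scope="session")
def toy_index(toy_merged):
    return build_index(toy_merged)


@pytest.fixture(scope="session")
def small_scenario():
    """A compact end-to-end fixture reused across tests."""
    return make_scenario(2, contig_len=40_000, n_events=2, n_background=40)


@pytest.fixture(scope="session")
def small_library(small_scenario):
    scen = small_scenario
    return simulate_capture_library(scen.implant, scen.construct, scen.params)


@pytest.fixture(scope="session")
def small_calls(small_scenario, small_library):
    scen = small_scenario
    idx = build_index(scen.merged)
    pairs = [align_pair(r.r1, r.r2, idx, r.read_id) for r in small_library.reads]
    return call_sample(pairs, scen.construct, "smp")


def make_junction_read(
    side: str, border: str, direction: str, genome_seq: str, construct,
    genome_pos: int = 5000, genome_part: int = 80, tdna_part: int = 70,
) -> str:
    """Synthesize an error-free junction-spanning read of a given geometry.

    The junction's construct-side coordinate sits just interior of the chosen
    border so border assignment by repeat proximity is unambiguous.
    """
    tdna = construct.tdna_seq
    # junction construct-coordinate: interior enough that a +/- tdna_part
    # piece stays on the contig, yet unambiguously nearest its border
    t_j = 100 if border == "LB" else construct.length - 101
    if side == "Left":
        g = genome_seq[genome_pos - genome_part : genome_pos]
        if direction == "Forward":
            x = tdna[t_j : t_j + tdna_part]
        else:
            x = revcomp(tdna[t_j - tdna_part + 1 : t_j + 1])
        return g + x
    g = genome_seq[genome_pos : genome_pos + genome_part]
    if direction == "Forward":
        x = tdna[t_j - tdna_part + 1 : t_j + 1]
    else:
        x = revcomp(tdna[t_j : t_j + tdna_part])
    return x + g


def all_junction_geometries():
    for side in ("Left", "Right"):
        for border in ("LB", "RB"):
            for direction in ("Forward", "Reverse"):
                yield side, border, direction
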