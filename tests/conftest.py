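"""Shared fixtures.

The session-scoped pea-like fixture is the desk-scale analog of the study
conditions: a ~9.5 Mbp genome carrying 13 enriched satellite families
(monomer lengths spanning 50-2094 bp) plus one dispersed retroelement,
0.8x reference reads, and 1e5 ChIP / 1e5 input reads.  Building and
analyzing it takes a few minutes, so every test that needs it shares one
run.
"""

from __future__ import annotations

import pytest

from censat.pipeline import PipelineConfig, run_approach_B
from censat.simulate import (
    PEALIKE_REFERENCE_COVERAGE,
    RetroelementSpec,
    SatelliteFamilySpec,
    build_genome,
    pealike_genome,
    simulate_chip_and_input,
    simulate_reference_reads,
)

PEALIKE_SEED = 101


@pytest.fixture(scope="session")
def pealike():
    """Genome + read sets of the pea-like fixture (no analysis yet)."""
    genome = pealike_genome(seed=PEALIKE_SEED)
    refs = simulate_reference_reads(
        genome, coverage=PEALIKE_REFERENCE_COVERAGE, seed=PEALIKE_SEED + 1
    )
    chip, inp = simulate_chip_and_input(
        genome, 100_000, 100_000, seed=PEALIKE_SEED + 2
    )
    return {"genome": genome, "refs": refs, "chip": chip, "input": inp}


@pytest.fixture(scope="session")
def pealike_result(pealike):
    """Approach-B analysis of the pea-like fixture."""
    genome = pealike["genome"]
    config = PipelineConfig(genome_size_mbp=genome.genome_size_mbp, seed=1)
    result = run_approach_B(
        pealike["chip"],
        pealike["input"],
        pealike["refs"],
        config,
        retro_library=[("crm_reference", genome.consensi["crm"])],
    )
    return result


@pytest.fixture(scope="module")
def small_world():
    """A small five-family world for pipeline tests: two enriched satellites,
    two ChIP-depleted satellites, one enriched retroelement, and a rare
    enriched satellite that approach A's top-N misses."""
    specs = [
        SatelliteFamilySpec("satE1", 120, 0.72, 2, (25, 25), 0.02, 40.0),
        SatelliteFamilySpec("satE2", 310, 0.74, 2, (14, 14), 0.02, 40.0),
        SatelliteFamilySpec("satB1", 180, 0.68, 2, (18, 18), 0.02, 1.0),
        SatelliteFamilySpec("satB2", 95, 0.70, 2, (30, 30), 0.02, 1.0),
        SatelliteFamilySpec("satR", 150, 0.75, 1, (16, 16), 0.02, 40.0),
        RetroelementSpec("retroE", 1500, 20, 0.02, 40.0, at_content=0.70),
    ]
    genome = build_genome(specs, background_length=800_000, seed=7)
    refs = simulate_reference_reads(genome, coverage=1.0, seed=8)
    chip, inp = simulate_chip_and_input(genome, 12_000, 12_000, seed=9)
    return {"genome": genome, "refs": refs, "chip": chip, "input": inp, "specs": specs}
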