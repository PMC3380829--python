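"""Synthetic-genome generator: construction, sampling and determinism."""

import numpy as np
import pytest

from censat.qc import run_qc
from censat.records import reverse_complement
from censat.simulate import (
    RetroelementSpec,
    SatelliteFamilySpec,
    build_genome,
    expected_enrichment,
    pealike_specs,
    random_consensus,
    simulate_chip_and_input,
    simulate_reference_reads,
)


def one_family(divergence=0.0, fold=1.0, copies=100, monomer=50):
    return SatelliteFamilySpec(
        "famA", monomer, 0.72, 1, (copies, copies), divergence, fold
    )


class TestBuildGenome:
    def test_zero_divergence_array_is_exact_head_to_tail(self):
        genome = build_genome([one_family()], background_length=50_000, seed=3)
        (fam, s, e, strand) = genome.annotations[0]
        assert fam == "famA" and e - s == 5000
        array = genome.sequence[s:e]
        if strand == "-":
            array = reverse_complement(array)
        cons = genome.consensi["famA"]
        assert array == cons * 100
        # zero-divergence arrays are exact rotations of the consensus at
        # every offset
        for off in (0, 13, 49):
            assert array[off : off + 50] == (cons + cons)[off : off + 50]

    def test_pealike_world_has_fourteen_families(self):
        specs = pealike_specs()
        genome = build_genome(specs, background_length=2_000_000, seed=5)
        fams = {a[0] for a in genome.annotations}
        assert len(fams) == 14
        sat = [s for s in specs if isinstance(s, SatelliteFamilySpec)]
        assert len(sat) == 13
        assert sorted(s.monomer_length for s in sat)[0] == 50
        assert sorted(s.monomer_length for s in sat)[-1] == 2094

    def test_consensus_at_content_close_to_spec(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            cons = random_consensus(50, 0.72, rng)
            at = sum(c in "AT" for c in cons) / 50
            assert abs(at - 0.72) <= 0.02

    def test_conservation_of_base_pairs(self):
        genome = build_genome(
            [one_family(), RetroelementSpec("r", 700, 4)], 60_000, seed=11
        )
        annotated = sum(e - s for _, s, e, _ in genome.annotations)
        assert annotated + 60_000 == len(genome.sequence)
        # annotations within bounds, non-overlapping
        prev_end = 0
        for _, s, e, _ in sorted(genome.annotations, key=lambda a: a[1]):
            assert 0 <= s < e <= len(genome.sequence)
            assert s >= prev_end
            prev_end = e

    def test_capacity_error(self):
        with pytest.raises(ValueError, match="density"):
            build_genome([one_family()], background_length=4000, seed=0)

    def test_retro_insertions_dispersed(self):
        genome = build_genome(
            [RetroelementSpec("r", 500, 6)], 100_000, seed=2
        )
        spans = sorted((s, e) for _, s, e, _ in genome.annotations)
        assert len(spans) == 6
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert s2 - e1 >= 200  # separated, never tandem


class TestReferenceReads:
    def test_read_count_follows_coverage_formula(self):
        genome = build_genome([one_family()], 995_000, seed=4)
        reads = simulate_reference_reads(genome, 0.48, 100, seed=1)
        assert len(reads) == round(0.48 * len(genome.sequence) / 100)
        assert all(len(r.sequence) == 100 for r in reads)

    def test_truth_fraction_matches_genome_proportion(self):
        genome = build_genome([one_family(copies=200)], 990_000, seed=4)
        p = genome.family_proportions()["famA"]
        reads = simulate_reference_reads(genome, 1.0, 100, seed=2)
        frac = sum(r.truth_family == "famA" for r in reads) / len(reads)
        se = (p * (1 - p) / len(reads)) ** 0.5
        assert abs(frac - p) < 4 * se + 1e-4

    def test_determinism_and_seed_sensitivity(self):
        genome = build_genome([one_family()], 50_000, seed=3)
        a = simulate_reference_reads(genome, 0.5, 100, seed=9)
        b = simulate_reference_reads(genome, 0.5, 100, seed=9)
        c = simulate_reference_reads(genome, 0.5, 100, seed=10)
        assert [r.sequence for r in a] == [r.sequence for r in b]
        assert [r.sequence for r in a] != [r.sequence for r in c]


class TestChipAndInput:
    def test_null_enrichment_when_all_weights_equal(self):
        genome = build_genome([one_family(fold=1.0, copies=200)], 200_000, seed=5)
        chip, inp = simulate_chip_and_input(genome, 30_000, 30_000, seed=6)
        pc = sum(r.truth_family == "famA" for r in chip) / len(chip)
        pi = sum(r.truth_family == "famA" for r in inp) / len(inp)
        se = (pc * (1 - pc) / len(chip)) ** 0.5
        assert abs(pc - pi) < 4 * se

    def test_realized_enrichment_matches_analytic_expectation(self):
        # one family at fold 50 occupying ~1% of the genome
        genome = build_genome(
            [one_family(fold=50.0, copies=200, monomer=50)], 990_000, seed=5
        )
        n = 100_000
        chip, inp = simulate_chip_and_input(genome, n, n, seed=6)
        pc = sum(r.truth_family == "famA" for r in chip) / n
        pi = sum(r.truth_family == "famA" for r in inp) / n
        expected = expected_enrichment(genome)["famA"]
        ratio = pc / pi
        # 3 binomial standard errors, propagated to the ratio
        se = ratio * (
            (1 - pc) / (n * pc) + (1 - pi) / (n * pi)
        ) ** 0.5
        assert abs(ratio - expected) < 3 * se

    def test_low_quality_rate_controls_sub20_bases(self):
        genome = build_genome([one_family()], 50_000, seed=1)
        chip, _ = simulate_chip_and_input(
            genome, 3000, 10, quality_model=(35, 3, 0.10), seed=2
        )
        quals = np.concatenate([np.asarray(r.qualities) for r in chip])
        frac = float((quals < 20).mean())
        assert abs(frac - 0.10) < 0.01

    def test_reads_are_fastq_like_and_qc_compatible(self):
        genome = build_genome([one_family()], 50_000, seed=1)
        chip, inp = simulate_chip_and_input(genome, 500, 500, seed=3)
        assert all(len(r.sequence) == 36 and len(r.qualities) == 36 for r in chip)
        result = run_qc(chip)
        assert result.n_surviving + result.n_dropped_quality == 500
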