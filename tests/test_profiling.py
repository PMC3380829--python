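"""Cluster characterization: assembly, periodicity, tandem checks, classes."""

import numpy as np
import pytest

from censat.profiling import (
    assemble_representative,
    at_content,
    classify_cluster,
    dotplot,
    estimate_monomer_length,
    library_similarity,
    pairwise_identity,
    periodic_core,
    verify_tandem_organization,
)
from censat.records import ReadRecord, reverse_complement

from oracle import brute_force_min_period

RNG = np.random.default_rng(23)


def rand_seq(n, rng=RNG):
    return "".join(rng.choice(list("ACGT"), size=n))


def mutate(seq, rate, rng):
    out = list(seq)
    for k in range(len(out)):
        if rng.random() < rate:
            out[k] = rng.choice([b for b in "ACGT" if b != out[k]])
    return "".join(out)


def tile_reads(source, read_len=100, step=20, prefix="t"):
    return [
        ReadRecord(f"{prefix}{k:03d}", source[s : s + read_len])
        for k, s in enumerate(range(0, len(source) - read_len + 1, step))
    ]


class TestMonomerLength:
    def test_matches_brute_force_period_on_exact_arrays(self):
        rng = np.random.default_rng(1)
        for m in range(1, 101):
            cons = rand_seq(m, rng)
            array = (cons * ((260 // m) + 2))[:260]
            expected = brute_force_min_period(array)
            got, ident = estimate_monomer_length(array, min_identity=0.999)
            assert got == expected, m
            assert ident == pytest.approx(1.0)

    def test_homopolymer_reports_period_one(self):
        assert estimate_monomer_length("A" * 200)[0] == 1

    def test_robust_to_point_divergence(self):
        rng = np.random.default_rng(2)
        cons = rand_seq(164, rng)
        array = "".join(mutate(cons, 0.05, rng) for _ in range(10))
        m, ident = estimate_monomer_length(array)
        assert m == 164
        assert ident > 0.85

    def test_aperiodic_sequence_reports_none(self):
        m, _ = estimate_monomer_length(rand_seq(1000))
        assert m is None

    def test_periodic_core_strips_flanking_tails(self):
        cons = rand_seq(100)
        left, right = rand_seq(300), rand_seq(250)
        seq = left + cons * 8 + right
        lo, hi = periodic_core(seq, 100)
        assert abs(lo - 300) <= 60
        assert abs(hi - (300 + 800)) <= 60
        # AT measured on the core reflects the array, not the flanks
        assert at_content(seq[lo:hi]) == pytest.approx(
            at_content(cons), abs=0.03
        )

    def test_periodic_core_of_pure_array_is_everything(self):
        cons = rand_seq(80)
        seq = cons * 10
        lo, hi = periodic_core(seq, 80)
        assert lo == 0 and hi == len(seq)


class TestAssembly:
    def test_reconstructs_multiple_periods_from_tiled_reads(self):
        cons = rand_seq(50)
        array = cons * 40  # 2000 bp tandem array
        reads = tile_reads(array[:900], read_len=80, step=15)
        contig = assemble_representative(reads)
        assert len(contig.sequence) >= 100  # >= 2 full periods
        m, _ = estimate_monomer_length(contig.sequence)
        assert m == 50
        assert not contig.low_confidence

    def test_long_monomer_contig_spans_monomer(self):
        cons = rand_seq(867)
        reads = tile_reads(cons * 4, read_len=100, step=25)
        contig = assemble_representative(reads)
        assert len(contig.sequence) >= 867
        assert estimate_monomer_length(contig.sequence)[0] == 867

    def test_single_read_cluster_degenerates_with_flag(self):
        read = ReadRecord("only", rand_seq(100))
        contig = assemble_representative([read])
        assert contig.sequence == read.sequence
        assert contig.low_confidence

    def test_mixed_orientation_reads_assemble(self):
        cons = rand_seq(120)
        array = cons * 8
        reads = tile_reads(array, read_len=100, step=30)
        flipped = [
            ReadRecord(r.read_id, reverse_complement(r.sequence))
            if k % 2
            else r
            for k, r in enumerate(reads)
        ]
        contig = assemble_representative(flipped)
        assert estimate_monomer_length(contig.sequence)[0] == 120


class TestTandemOrganization:
    def test_tandem_array_is_head_to_tail(self):
        cons = rand_seq(150)
        check = verify_tandem_organization(cons * 5, cons)
        assert check.head_to_tail and check.n_copies >= 4

    def test_dispersed_copies_are_not(self):
        cons = rand_seq(150)
        seq = rand_seq(400) + cons + rand_seq(5 * 150) + cons + rand_seq(400)
        check = verify_tandem_organization(seq, cons)
        assert not check.head_to_tail
        assert check.n_copies == 2

    def test_absent_consensus_reports_zero_copies(self):
        check = verify_tandem_organization(rand_seq(2000), rand_seq(150))
        assert not check.head_to_tail and check.n_copies == 0

    def test_inverted_adjacent_copies_do_not_count(self):
        cons = rand_seq(150)
        seq = cons + reverse_complement(cons)
        assert not verify_tandem_organization(seq, cons).head_to_tail


class TestATContent:
    @pytest.mark.parametrize(
        "seq,expected", [("ATAT", 1.0), ("ACGT", 0.5), ("GGCC", 0.0)]
    )
    def test_examples(self, seq, expected):
        assert at_content(seq) == pytest.approx(expected)

    def test_n_bases_excluded(self):
        assert at_content("ATNN") == pytest.approx(1.0)
        assert at_content("NNNN") is None

    def test_uniform_random_sequence_near_half(self):
        n = 30_000
        seq = "".join(np.random.default_rng(9).choice(list("ACGT"), size=n))
        se = (0.25 / n) ** 0.5
        assert abs(at_content(seq) - 0.5) < 3 * se


class TestClassification:
    def test_periodic_tandem_is_satellite(self):
        cons = rand_seq(100)
        cls, flags = classify_cluster(cons * 6, 100, True)
        assert cls == "satellite" and flags == ""

    def test_retro_similarity_wins_for_aperiodic_contig(self):
        rng = np.random.default_rng(4)
        element = rand_seq(2000, rng)
        contig = mutate(element[300:1500], 0.05, rng)
        cls, _ = classify_cluster(contig, None, False, [("crm", element)])
        assert cls == "ltr_retroelement"

    def test_conflict_flagged_and_retro_wins(self):
        cons = rand_seq(100)
        cls, flags = classify_cluster(cons * 6, 100, True, [("crm", cons * 6)])
        assert cls == "ltr_retroelement"
        assert "conflict" in flags

    def test_no_evidence_is_unclassified(self):
        assert classify_cluster(rand_seq(800), None, False)[0] == "unclassified"

    def test_library_similarity_detects_reverse_complement(self):
        element = rand_seq(1500)
        ident, cov, name = library_similarity(
            reverse_complement(element[200:1200]), [("crm", element)]
        )
        assert name == "crm" and ident > 0.99 and cov > 0.99


class TestDotplot:
    def test_self_pair_has_main_diagonal(self):
        seq = rand_seq(300)
        dp = dotplot([("a", seq)], window=50)
        assert ("a", 0, "a", 0, "+") in dp.matches
        assert ("a", 100, "a", 100, "+") in dp.matches

    def test_unrelated_sequences_show_nothing(self):
        dp = dotplot([("a", rand_seq(400)), ("b", rand_seq(400))], window=50)
        assert not any(m[0] != m[2] for m in dp.matches)

    def test_shared_fragment_block_confined(self):
        core = rand_seq(150)
        a = rand_seq(100) + core + rand_seq(100)
        b = rand_seq(200) + core + rand_seq(200)
        dp = dotplot([("a", a), ("b", b)], window=50)
        cross = [m for m in dp.matches if m[0] == "a" and m[2] == "b"]
        assert cross
        # windows qualify once core overlap plus chance flank matches reach
        # 45 of 50 bases, so the block edge is fuzzy by a dozen bases
        assert all(85 <= i <= 215 and 185 <= j <= 315 for _, i, _, j, s in cross)

    def test_symmetry_under_pair_swap(self):
        a, b = rand_seq(200), rand_seq(200)
        shared = rand_seq(80)
        a = a[:60] + shared + a[140:]
        b = b[:100] + shared + b[180:]
        dp = dotplot([("a", a), ("b", b)], window=50)
        ab = {(i, j, s) for x, i, y, j, s in dp.matches if (x, y) == ("a", "b")}
        ba = {(j, i, s) for x, i, y, j, s in dp.matches if (x, y) == ("b", "a")}
        assert ab == ba


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("ACGTACGT", "ACGTACGT") == pytest.approx(100.0)

    def test_single_substitution(self):
        assert pairwise_identity("ACGT", "ACGA") == pytest.approx(75.0)

    def test_internal_gap_counts_as_column(self):
        assert pairwise_identity("ACGTACGT", "ACGACGT") == pytest.approx(100 * 7 / 8)

    def test_end_gaps_are_free(self):
        assert pairwise_identity("AAACGTACGT", "CGTACGT") == pytest.approx(100.0)

    def test_protein_alphabet(self):
        assert pairwise_identity("MARTKQTA", "MARTKQSA", alphabet="protein") == (
            pytest.approx(100 * 7 / 8)
        )
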