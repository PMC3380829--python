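"""Similarity-graph clustering: edges, components, ordering, assignment."""

import numpy as np
import pytest

from censat.clustering import (
    SimilarityParams,
    assign_read_to_cluster,
    build_similarity_graph,
    cluster_components,
    select_top_clusters,
)
from censat.records import MatchHit, ReadRecord, reverse_complement
from censat.simulate import (
    SatelliteFamilySpec,
    build_genome,
    simulate_reference_reads,
)

RNG = np.random.default_rng(17)


def rand_seq(n, rng=RNG):
    return "".join(rng.choice(list("ACGT"), size=n))


def tile_reads(source, read_len=100, step=25, prefix="t"):
    reads = []
    for k, s in enumerate(range(0, len(source) - read_len + 1, step)):
        reads.append(ReadRecord(f"{prefix}{k:03d}", source[s : s + read_len]))
    return reads


class TestEdges:
    def test_identical_reads_share_an_edge(self):
        r1, r2 = ReadRecord("a", rand_seq(100)), None
        r2 = ReadRecord("b", r1.sequence)
        g = build_similarity_graph([r1, r2])
        assert g.has_edge("a", "b")

    def test_unrelated_families_stay_separate(self):
        fam1 = tile_reads(rand_seq(600), prefix="x")
        fam2 = tile_reads(rand_seq(600), prefix="y")
        g = build_similarity_graph(fam1 + fam2)
        assert not any(
            a.startswith("x") != b.startswith("x") for a, b in g.edges
        )

    def test_shared_monomer_fragment_links_families(self):
        # a TR-11/TR-19-like situation: the long monomer embeds a fragment
        # of the short one, creating inter-family edges (merge risk)
        short = rand_seq(300)
        long_monomer = rand_seq(250) + short[50:200] + rand_seq(250)
        fam_short = tile_reads(short * 2, prefix="s")
        fam_long = tile_reads(long_monomer, prefix="l")
        g = build_similarity_graph(fam_short + fam_long)
        assert any(a[0] != b[0] for a, b in g.edges)

    def test_reverse_complement_overlap_detected(self):
        seq = rand_seq(300)
        a = ReadRecord("a", seq[0:100])
        b = ReadRecord("b", reverse_complement(seq[30:130]))
        assert build_similarity_graph([a, b]).has_edge("a", "b")


class TestComponents:
    def test_proportions_and_ordering(self):
        big = tile_reads(rand_seq(800), step=10, prefix="a")[:30]
        small = tile_reads(rand_seq(400), step=10, prefix="b")[:10]
        isolated = [ReadRecord(f"z{k}", rand_seq(100)) for k in range(60)]
        reads = big + small + isolated
        clusters = cluster_components(build_similarity_graph(reads), len(reads))
        assert clusters[0].size == 30 and clusters[1].size == 10
        assert clusters[0].genome_proportion == pytest.approx(0.30)
        assert clusters[1].genome_proportion == pytest.approx(0.10)
        assert clusters[0].cluster_id < clusters[1].cluster_id
        # partition: every read in exactly one cluster; proportions sum to 1
        seen = [rid for cl in clusters for rid in cl.member_ids]
        assert sorted(seen) == sorted(r.read_id for r in reads)
        assert sum(cl.genome_proportion for cl in clusters) == pytest.approx(1.0)

    def test_tie_broken_by_smallest_member_id(self):
        pair1 = [ReadRecord("m1", rand_seq(100))]
        pair1.append(ReadRecord("m2", pair1[0].sequence))
        pair2 = [ReadRecord("k1", rand_seq(100))]
        pair2.append(ReadRecord("k2", pair2[0].sequence))
        clusters = cluster_components(build_similarity_graph(pair1 + pair2))
        assert clusters[0].member_ids[0] == "k1"

    def test_order_invariance(self):
        reads = tile_reads(rand_seq(500), prefix="a") + [
            ReadRecord(f"b{k}", rand_seq(100)) for k in range(20)
        ]
        part1 = {
            frozenset(cl.member_ids)
            for cl in cluster_components(build_similarity_graph(reads))
        }
        rng = np.random.default_rng(3)
        shuffled = list(reads)
        rng.shuffle(shuffled)
        part2 = {
            frozenset(cl.member_ids)
            for cl in cluster_components(build_similarity_graph(shuffled))
        }
        assert part1 == part2

    def test_truth_recovery_on_simulated_families(self):
        specs = [
            SatelliteFamilySpec("f1", 150, 0.70, 1, (60, 60), 0.05, 1.0),
            SatelliteFamilySpec("f2", 400, 0.75, 1, (25, 25), 0.05, 1.0),
            SatelliteFamilySpec("f3", 90, 0.65, 1, (90, 90), 0.05, 1.0),
        ]
        genome = build_genome(specs, background_length=40_000, seed=21)
        reads = [
            r
            for r in simulate_reference_reads(genome, 1.5, 100, seed=22)
            if r.truth_family != "background"
        ]
        clusters = cluster_components(build_similarity_graph(reads), len(reads))
        # each family maps to exactly one reportable cluster; the remainder
        # are tiny array-edge fragments below the profiling size floor
        main = [cl for cl in clusters if cl.size >= 5]
        assert len(main) == 3
        by_id = {r.read_id: r.truth_family for r in reads}
        captured = 0
        for cl in main:
            fams = [by_id[m] for m in cl.member_ids]
            purity = max(fams.count(f) for f in set(fams)) / len(fams)
            assert purity >= 0.99
            captured += cl.size
        assert captured >= 0.95 * len(reads)


class TestTopAndAssignment:
    def make_clusters(self):
        g = build_similarity_graph(
            tile_reads(rand_seq(600), prefix="a") + tile_reads(rand_seq(300), prefix="b")
        )
        return cluster_components(g)

    def test_select_top_clusters(self):
        clusters = self.make_clusters()
        assert select_top_clusters(clusters, 1000) == clusters
        assert select_top_clusters(clusters, 1) == clusters[:1]

    def test_assignment_prefers_best_hit_then_bigger_cluster(self):
        ref_to_cluster = {"r1": "CL0001", "r2": "CL0002"}
        props = {"CL0001": 0.3, "CL0002": 0.1}

        def hit(ref, e, b=0):
            return MatchHit("q", ref, 0, "+", e, b)

        assert (
            assign_read_to_cluster([hit("r1", 1), hit("r2", 0)], ref_to_cluster, props)
            == "CL0002"
        )
        assert (
            assign_read_to_cluster([hit("r1", 1), hit("r2", 1)], ref_to_cluster, props)
            == "CL0001"
        )
        assert assign_read_to_cluster([], ref_to_cluster, props) is None
        assert (
            assign_read_to_cluster(
                [hit("unclustered", 0)], ref_to_cluster, props
            )
            is None
        )
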