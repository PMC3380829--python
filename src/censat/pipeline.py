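"""End-to-end orchestration of the two enrichment analyses.

Approach A (top-abundance clusters): cluster a random sample of reference
reads, keep the top-N clusters by genome representation, assign every
ChIP/input read to at most one cluster (best hit; ties resolved toward the
cluster with higher genome representation), and compute per-cluster
enrichment.  This resolves all major repeat families but misses low-copy
sequences.

Approach B (per-read enrichment): compute the ChIP enrichment of every
individual reference read, select reads at >= 10-fold enrichment, and
cluster only those.  This concentrates the clustering on putatively
CenH3-associated sequences regardless of their abundance and therefore
also recovers rare enriched families.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .clustering import (
    SimilarityParams,
    build_similarity_graph,
    cluster_components,
    select_top_clusters,
)
from .enrichment import EnrichmentRecord, compute_enrichment, make_records
from .mapping import Matcher, MatchParams, ReferenceIndex, map_and_count
from .profiling import (
    assemble_representative,
    at_content,
    classify_cluster,
    estimate_monomer_length,
    library_similarity,
    periodic_core,
    verify_tandem_organization,
)
from .qc import QCParams, QCResult, run_qc
from .quantify import round_half_up
from .records import FamilyReport, ReadRecord, RepeatCluster


@dataclass
class PipelineConfig:
    qc: QCParams = field(default_factory=QCParams)
    match: MatchParams = field(default_factory=MatchParams)
    similarity: SimilarityParams = field(default_factory=SimilarityParams)
    enrichment_threshold: float = 10.0
    zero_policy: str = "infinite"
    top_n_clusters: int = 1000
    reference_sample_size: int = 2_000_000
    min_cluster_size: int = 5
    multi_hit_policy: str = "count_all"
    genome_size_mbp: float = 4300.0
    seed: int = 0

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "PipelineConfig":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            data = json.loads(source)
        else:
            with open(source) as fh:
                data = json.load(fh)
        data["qc"] = QCParams(**data.get("qc", {}))
        data["match"] = MatchParams(**data.get("match", {}))
        data["similarity"] = SimilarityParams(**data.get("similarity", {}))
        return cls(**data)


@dataclass
class PipelineResult:
    report: pd.DataFrame
    clusters: List[RepeatCluster]
    qc_chip: QCResult
    qc_input: QCResult
    records: List[EnrichmentRecord]
    log: Dict[str, float]
    contigs: Dict[str, str] = field(default_factory=dict)


REPORT_COLUMNS = [
    "family_id",
    "cluster_id",
    "classification",
    "enrichment",
    "genome_proportion_pct",
    "total_mbp",
    "monomer_length",
    "at_content",
    "n_reads",
    "chip_count",
    "input_count",
    "flags",
]


def _profile_cluster(
    cluster: RepeatCluster,
    reads_by_id: Dict[str, ReadRecord],
    retro_library: Sequence[Tuple[str, str]],
    naming_library: Sequence[Tuple[str, str]],
    min_cluster_size: int,
):
    """Representative contig, monomer, tandem check and classification for
    one cluster; clusters below the size floor stay unprofiled."""
    if cluster.size < min_cluster_size:
        return None
    members = [reads_by_id[m] for m in cluster.member_ids]
    contig = assemble_representative(members)
    monomer, _ = estimate_monomer_length(contig.sequence)
    head_to_tail = False
    measured = contig.sequence
    if monomer is not None:
        # judge tandem structure on the repeating core of the contig,
        # excluding flank sequence brought in by junction reads
        lo, hi = periodic_core(contig.sequence, monomer)
        measured = contig.sequence[lo:hi]
        consensus = measured[:monomer]
        check = verify_tandem_organization(measured, consensus)
        # a linear contig that repeats at shift m necessarily spans a
        # copy junction (two adjacent same-orientation copies), so
        # periodicity itself is head-to-tail evidence; the explicit probe
        # check needs a second full copy, which a tiling-gap-limited
        # contig of a long monomer may not contain
        head_to_tail = check.head_to_tail or len(measured) >= monomer + 20
    classification, flags = classify_cluster(
        contig.sequence, monomer, head_to_tail, retro_library
    )
    # family AT content over all member reads: a much larger base sample
    # than the representative contig, whose short-monomer mosaics reuse
    # only a handful of reads
    member_at = at_content("".join(m.sequence for m in members))
    if contig.low_confidence:
        flags = (flags + ";" if flags else "") + "low_confidence_contig"
    family_id = cluster.cluster_id
    if naming_library:
        ident, cov, name = library_similarity(contig.sequence, naming_library)
        if name is not None and ident >= 0.8:
            family_id = name
    return {
        "contig": contig.sequence,
        "monomer": monomer if classification == "satellite" else None,
        "head_to_tail": head_to_tail,
        "classification": classification,
        "flags": flags,
        "family_id": family_id,
        "at": member_at,
    }


def _build_report(
    clusters: Sequence[RepeatCluster],
    profiles: Dict[str, Optional[dict]],
    genome_size_mbp: float,
) -> pd.DataFrame:
    rows = []
    for cl in clusters:
        prof = profiles.get(cl.cluster_id)
        pct = 100.0 * cl.genome_proportion
        rows.append(
            {
                "family_id": prof["family_id"] if prof else cl.cluster_id,
                "cluster_id": cl.cluster_id,
                "classification": prof["classification"] if prof else cl.classification,
                "enrichment": cl.enrichment,
                "genome_proportion_pct": pct,
                "total_mbp": round_half_up(pct / 100.0 * genome_size_mbp),
                "monomer_length": prof["monomer"] if prof else None,
                "at_content": prof["at"] if prof else None,
                "n_reads": cl.size,
                "chip_count": cl.chip_count,
                "input_count": cl.input_count,
                "flags": prof["flags"] if prof else "",
            }
        )
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if len(df):
        df = df.sort_values(
            by=["enrichment", "genome_proportion_pct", "cluster_id"],
            ascending=[False, False, True],
            kind="stable",
        ).reset_index(drop=True)
    return df


def run_approach_A(
    chip_reads: Sequence[ReadRecord],
    input_reads: Sequence[ReadRecord],
    reference_reads: Sequence[ReadRecord],
    config: Optional[PipelineConfig] = None,
    retro_library: Sequence[Tuple[str, str]] = (),
    naming_library: Sequence[Tuple[str, str]] = (),
) -> PipelineResult:
    """Top-cluster enrichment: cluster a reference sample, assign reads,
    compute per-cluster enrichment, profile and report."""
    config = config or PipelineConfig()
    qc_chip = run_qc(chip_reads, config.qc)
    qc_input = run_qc(input_reads, config.qc)
    if not qc_chip.reads or not qc_input.reads:
        raise ValueError(
            "no reads survive QC "
            f"(chip {qc_chip.n_surviving}/{qc_chip.n_input}, "
            f"input {qc_input.n_surviving}/{qc_input.n_input})"
        )

    rng = np.random.default_rng(config.seed)
    n_sample = min(config.reference_sample_size, len(reference_reads))
    sample_idx = np.sort(rng.choice(len(reference_reads), size=n_sample, replace=False))
    sample = [reference_reads[int(i)] for i in sample_idx]

    graph = build_similarity_graph(sample, config.similarity)
    clusters = cluster_components(graph, total_reads=n_sample)
    top = select_top_clusters(clusters, config.top_n_clusters)

    index = ReferenceIndex(sample)
    matcher = Matcher(index, config.match)
    ref_to_cluster: Dict[int, str] = {}
    id_to_idx = {rid: k for k, rid in enumerate(index.ref_ids)}
    proportions = {cl.cluster_id: cl.genome_proportion for cl in top}
    for cl in top:
        for rid in cl.member_ids:
            ref_to_cluster[id_to_idx[rid]] = cl.cluster_id

    def assign_all(reads: Sequence[ReadRecord]) -> Tuple[Dict[str, float], int]:
        counts: Dict[str, float] = {}
        n_mapped = 0
        for read in reads:
            hits = matcher.match_sequence(read.sequence)
            best_key = None
            cands = set()
            for r, s, e, b, o in hits:
                cid = ref_to_cluster.get(r)
                if cid is None:
                    continue
                key = (e, b)
                if best_key is None or key < best_key:
                    best_key, cands = key, {cid}
                elif key == best_key:
                    cands.add(cid)
            if not cands:
                continue
            n_mapped += 1
            chosen = min(cands, key=lambda c: (-proportions.get(c, 0.0), c))
            counts[chosen] = counts.get(chosen, 0.0) + 1.0
        return counts, n_mapped

    chip_counts, chip_mapped = assign_all(qc_chip.reads)
    input_counts, input_mapped = assign_all(qc_input.reads)

    C, I = qc_chip.n_surviving, qc_input.n_surviving
    for cl in top:
        cl.chip_count = chip_counts.get(cl.cluster_id, 0.0)
        cl.input_count = input_counts.get(cl.cluster_id, 0.0)
        cl.enrichment = compute_enrichment(
            cl.chip_count, C, cl.input_count, I, config.zero_policy
        )

    reads_by_id = {r.read_id: r for r in sample}
    profiles = {}
    contigs = {}
    for cl in top:
        prof = _profile_cluster(
            cl, reads_by_id, retro_library, naming_library, config.min_cluster_size
        )
        profiles[cl.cluster_id] = prof
        if prof:
            cl.classification = prof["classification"]
            contigs[cl.cluster_id] = prof["contig"]

    records = [
        EnrichmentRecord(cl.cluster_id, cl.chip_count, cl.input_count, C, I, cl.enrichment)
        for cl in top
    ]
    report = _build_report(top, profiles, config.genome_size_mbp)
    log = {
        "chip_input_reads": qc_chip.n_input,
        "chip_dropped_short": qc_chip.n_dropped_short,
        "chip_dropped_quality": qc_chip.n_dropped_quality,
        "chip_surviving": C,
        "chip_assigned": chip_mapped,
        "chip_unassigned": C - chip_mapped,
        "input_input_reads": qc_input.n_input,
        "input_dropped_short": qc_input.n_dropped_short,
        "input_dropped_quality": qc_input.n_dropped_quality,
        "input_surviving": I,
        "input_assigned": input_mapped,
        "input_unassigned": I - input_mapped,
        "n_reference_sampled": n_sample,
        "n_clusters": len(clusters),
        "n_top_clusters": len(top),
    }
    return PipelineResult(report, top, qc_chip, qc_input, records, log, contigs)


def per_reference_enrichment(
    chip_reads: Sequence[ReadRecord],
    input_reads: Sequence[ReadRecord],
    matcher: Matcher,
    zero_policy: str = "infinite",
    multi_hit_policy: str = "count_all",
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, Dict[str, float]]:
    """Per-reference-read (chip counts, input counts, enrichment) arrays."""
    C, I = len(chip_reads), len(input_reads)
    chip_counts, chip_mapped, _ = map_and_count(chip_reads, matcher, multi_hit_policy)
    input_counts, input_mapped, _ = map_and_count(input_reads, matcher, multi_hit_policy)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = (chip_counts / C) / (input_counts / I)
    if zero_policy == "infinite":
        e[(input_counts == 0) & (chip_counts > 0)] = math.inf
        e[(input_counts == 0) & (chip_counts == 0)] = 0.0
    elif zero_policy == "pseudocount":
        zero = input_counts == 0
        e[zero] = (chip_counts[zero] / C) / (1.0 / I)
    else:
        raise ValueError(f"unknown zero policy: {zero_policy}")
    log = {"chip_mapped": chip_mapped, "input_mapped": input_mapped}
    return chip_counts, input_counts, e, log


def run_approach_B(
    chip_reads: Sequence[ReadRecord],
    input_reads: Sequence[ReadRecord],
    reference_reads: Sequence[ReadRecord],
    config: Optional[PipelineConfig] = None,
    retro_library: Sequence[Tuple[str, str]] = (),
    naming_library: Sequence[Tuple[str, str]] = (),
) -> PipelineResult:
    """Per-read enrichment, selection at the >= 10-fold cutoff, clustering
    of enriched reads only, profiling and reporting."""
    config = config or PipelineConfig()
    qc_chip = run_qc(chip_reads, config.qc)
    qc_input = run_qc(input_reads, config.qc)
    if not qc_chip.reads or not qc_input.reads:
        raise ValueError(
            "no reads survive QC "
            f"(chip {qc_chip.n_surviving}/{qc_chip.n_input}, "
            f"input {qc_input.n_surviving}/{qc_input.n_input})"
        )
    index = ReferenceIndex(reference_reads)
    matcher = Matcher(index, config.match)
    C, I = qc_chip.n_surviving, qc_input.n_surviving
    chip_counts, input_counts, e, map_log = per_reference_enrichment(
        qc_chip.reads,
        qc_input.reads,
        matcher,
        config.zero_policy,
        config.multi_hit_policy,
    )
    n_refs = index.n_refs
    selected = np.flatnonzero(e >= config.enrichment_threshold)
    enriched_pct = round(100.0 * selected.size / n_refs, 2) if n_refs else 0.0

    enriched_reads = [reference_reads[int(k)] for k in selected]
    graph = build_similarity_graph(enriched_reads, config.similarity)
    clusters = cluster_components(graph, total_reads=n_refs)

    id_to_idx = {rid: k for k, rid in enumerate(index.ref_ids)}
    for cl in clusters:
        idx = [id_to_idx[m] for m in cl.member_ids]
        cl.chip_count = float(chip_counts[idx].sum())
        cl.input_count = float(input_counts[idx].sum())
        cl.enrichment = compute_enrichment(
            cl.chip_count, C, cl.input_count, I, config.zero_policy
        )

    reads_by_id = {r.read_id: r for r in enriched_reads}
    profiles = {}
    contigs = {}
    for cl in clusters:
        prof = _profile_cluster(
            cl, reads_by_id, retro_library, naming_library, config.min_cluster_size
        )
        profiles[cl.cluster_id] = prof
        if prof:
            cl.classification = prof["classification"]
            contigs[cl.cluster_id] = prof["contig"]

    records = make_records(
        [index.ref_ids[int(k)] for k in range(n_refs)],
        chip_counts.tolist(),
        input_counts.tolist(),
        C,
        I,
        config.zero_policy,
    )
    report = _build_report(clusters, profiles, config.genome_size_mbp)
    log = {
        "chip_input_reads": qc_chip.n_input,
        "chip_dropped_short": qc_chip.n_dropped_short,
        "chip_dropped_quality": qc_chip.n_dropped_quality,
        "chip_surviving": C,
        "chip_mapped": map_log["chip_mapped"],
        "chip_unmapped": C - map_log["chip_mapped"],
        "input_input_reads": qc_input.n_input,
        "input_dropped_short": qc_input.n_dropped_short,
        "input_dropped_quality": qc_input.n_dropped_quality,
        "input_surviving": I,
        "input_mapped": map_log["input_mapped"],
        "input_unmapped": I - map_log["input_mapped"],
        "n_reference_reads": n_refs,
        "n_enriched_reads": int(selected.size),
        "enriched_pct": enriched_pct,
        "n_enriched_clusters": len(clusters),
    }
    return PipelineResult(report, clusters, qc_chip, qc_input, records, log, contigs)


def write_report_tsv(result: PipelineResult, path) -> None:
    result.report.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_membership_tsv(result: PipelineResult, path) -> None:
    rows = [
        {"cluster_id": cl.cluster_id, "read_id": rid}
        for cl in result.clusters
        for rid in cl.member_ids
    ]
    pd.DataFrame(rows, columns=["cluster_id", "read_id"]).to_csv(
        path, sep="\t", index=False
    )
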