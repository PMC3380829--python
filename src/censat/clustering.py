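"""Graph-based clustering of reference reads into repeat families.

Reads become nodes; an edge joins two reads whose best overlap alignment
(either strand) covers at least ``min_overlap_fraction`` of the shorter
read at ``min_identity`` or better.  Repeat families emerge as connected
components, because reads drawn from the same repeat tile its consensus
and overlap each other transitively.

Candidate pairs are pre-filtered by shared exact k-mers and scored on the
best ungapped diagonal (candidate diagonals come from the shared k-mers);
this matches the substitution-dominated divergence structure of satellite
arrays.  The same machinery serves both clustering contexts: top-abundance
clusters from a random reference sample, and clusters built only from
ChIP-enriched reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from ._kernels import encode, rolling_codes
from .records import MatchHit, ReadRecord, RepeatCluster, reverse_complement


@dataclass(frozen=True)
class SimilarityParams:
    min_identity: float = 0.90
    min_overlap_fraction: float = 0.55
    kmer_length: int = 13

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1 or not 0 < self.min_overlap_fraction <= 1:
            raise ValueError("similarity thresholds must be in (0, 1]")


def overlap_identity(
    a: np.ndarray, b: np.ndarray, diags: Iterable[int], min_overlap: int
) -> Tuple[float, int]:
    """Best (identity, overlap) over candidate ungapped diagonals.

    A diagonal d aligns a[i] with b[i - d]; overlap shorter than
    ``min_overlap`` is skipped.
    """
    best_id, best_ov = 0.0, 0
    la, lb = a.shape[0], b.shape[0]
    for d in diags:
        a_lo = max(0, d)
        a_hi = min(la, lb + d)
        ov = a_hi - a_lo
        if ov < min_overlap:
            continue
        ident = float(np.count_nonzero(a[a_lo:a_hi] == b[a_lo - d : a_hi - d])) / ov
        if ident > best_id or (ident == best_id and ov > best_ov):
            best_id, best_ov = ident, ov
    return best_id, best_ov


def _kmer_diag_candidates(enc_reads: List[np.ndarray], k: int):
    """Candidate (i, j, strand, diag) tuples from shared exact k-mers.

    Reads are indexed forward and reverse-complemented; each unordered read
    pair is reported once per (strand, diagonal)."""
    buckets: Dict[int, List[Tuple[int, int, int]]] = {}
    for i, enc in enumerate(enc_reads):
        fwd = rolling_codes(enc, k)
        rc = rolling_codes(np.where(enc > 3, np.uint8(4), (3 - enc).astype(np.uint8))[::-1], k)
        for strand, vals in ((0, fwd), (1, rc)):
            for p in range(vals.shape[0]):
                v = int(vals[p])
                if v >= 0:
                    buckets.setdefault(v, []).append((i, strand, p))
    lengths = [e.shape[0] for e in enc_reads]
    pairs: Dict[Tuple[int, int, int], set] = {}
    for entries in buckets.values():
        if len(entries) < 2:
            continue
        fwd_entries = [(i, p) for i, s, p in entries if s == 0]
        rev_entries = [(i, p) for i, s, p in entries if s == 1]
        # forward-forward pairs
        for x in range(len(fwd_entries)):
            ix, px = fwd_entries[x]
            for y in range(x + 1, len(fwd_entries)):
                iy, py = fwd_entries[y]
                if ix == iy:
                    continue
                a, pa, b, pb = (ix, px, iy, py) if ix < iy else (iy, py, ix, px)
                pairs.setdefault((a, b, 0), set()).add(pa - pb)
        # forward vs reverse-complement pairs; diag is kept in the frame
        # a = fwd(smaller index), b = revcomp(larger index)
        for ix, px in fwd_entries:
            for iy, py in rev_entries:
                if ix == iy:
                    continue
                if ix < iy:
                    pairs.setdefault((ix, iy, 1), set()).add(px - py)
                else:
                    pa = lengths[iy] - k - py
                    pb = lengths[ix] - k - px
                    pairs.setdefault((iy, ix, 1), set()).add(pa - pb)
    return pairs


def build_similarity_graph(
    reads: Sequence[ReadRecord],
    params: Optional[SimilarityParams] = None,
) -> nx.Graph:
    """Mutual-similarity graph over reads (nodes = read ids)."""
    params = params or SimilarityParams()
    graph = nx.Graph()
    for r in reads:
        graph.add_node(r.read_id)
    if len(reads) < 2:
        return graph
    enc_fwd = [encode(r.sequence) for r in reads]
    enc_rc = [
        np.where(e > 3, np.uint8(4), (3 - e).astype(np.uint8))[::-1] for e in enc_fwd
    ]
    pairs = _kmer_diag_candidates(enc_fwd, params.kmer_length)
    for (i, j, strand), diags in pairs.items():
        a = enc_fwd[i]
        b = enc_fwd[j] if strand == 0 else enc_rc[j]
        min_ov = int(np.ceil(params.min_overlap_fraction * min(a.shape[0], b.shape[0])))
        ident, ov = overlap_identity(a, b, sorted(diags), min_ov)
        if ov >= min_ov and ident >= params.min_identity:
            graph.add_edge(reads[i].read_id, reads[j].read_id)
    return graph


def cluster_components(
    graph: nx.Graph, total_reads: Optional[int] = None
) -> List[RepeatCluster]:
    """Connected components as clusters, sorted by descending genome
    proportion (= members / total analyzed reads); ties broken by the
    smallest member read id.  Singletons are included."""
    total = total_reads if total_reads is not None else graph.number_of_nodes()
    comps = [sorted(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    clusters = []
    for k, members in enumerate(comps, start=1):
        clusters.append(
            RepeatCluster(
                cluster_id=f"CL{k:04d}",
                member_ids=members,
                genome_proportion=len(members) / total if total else 0.0,
            )
        )
    return clusters


def select_top_clusters(
    clusters: Sequence[RepeatCluster], n: int = 1000
) -> List[RepeatCluster]:
    """First n clusters of the (already sorted) cluster list."""
    return list(clusters[: max(0, n)])


def assign_read_to_cluster(
    hits: Sequence[MatchHit],
    ref_to_cluster: Dict[str, str],
    cluster_proportions: Dict[str, float],
) -> Optional[str]:
    """Single-cluster assignment of one query given its reference hits.

    The cluster of the best hit wins (fewest difference events, then fewest
    indel bases); exact ties across clusters go to the cluster with the
    higher genome representation, then the lower cluster id.  Returns None
    for unassigned (no hits into any clustered reference).
    """
    best_key = None
    candidates: set = set()
    for h in hits:
        cid = ref_to_cluster.get(h.reference_id)
        if cid is None:
            continue
        key = (h.n_differences, h.indel_bases)
        if best_key is None or key < best_key:
            best_key = key
            candidates = {cid}
        elif key == best_key:
            candidates.add(cid)
    if not candidates:
        return None
    return min(candidates, key=lambda c: (-cluster_proportions.get(c, 0.0), c))
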