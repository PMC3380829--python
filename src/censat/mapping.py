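"""Approximate matching of short reads against unassembled reference reads.

Semantics follow the bounded-difference model: the query must align over
its full length to a window of a reference read with at most
``max_differences`` difference events, where a mismatch is one event and a
contiguous indel run of L bases is one event, the total indel length being
capped by ``max_total_indel_bases``.  Both strands are searched.

Candidate windows are found with exact seeds and verified with a bitmask
dynamic program (:mod:`censat._kernels`).  For the default bounds
(2 events, 4 indel bases) over 31 nt queries the seed scheme is complete:

* three non-overlapping 10-mers at query offsets 0, 10, 20 cover every
  alignment in which some seed span is untouched by an event (all
  substitution-only alignments in particular), and
* two supplementary *joint* seed pairs -- (q[0:7] with q[13:19]) and
  (q[24:31] with q[10:16]), required to co-occur on diagonals within +/-4
  -- cover the remaining case of an insertion run straddling a seed
  boundary, which can break two 10-mer seeds with a single event.

A case analysis (checked empirically against the brute-force oracle in the
test suite) shows every alignment within the bounds leaves one of these
seed patterns intact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import _kernels
from ._kernels import encode, hamming_at, lattice_dp, lattice_masks, rolling_codes
from .records import MatchHit, ReadRecord, reverse_complement

SEPARATOR = 16  # N bases between concatenated reference reads


@dataclass(frozen=True)
class MatchParams:
    max_differences: int = 2
    max_total_indel_bases: int = 4
    search_both_strands: bool = True

    def __post_init__(self) -> None:
        if self.max_differences < 0 or self.max_total_indel_bases < 0:
            raise ValueError("difference bounds must be non-negative")


def _seed_code(enc: np.ndarray, start: int, k: int) -> int:
    v = 0
    for j in range(k):
        c = int(enc[start + j])
        if c > 3:
            return -1
        v |= c << (2 * j)
    return v


class _KmerIndex:
    """Exact k-mer -> sorted global positions over the concatenated references."""

    def __init__(self, codes: np.ndarray, k: int):
        self.k = k
        vals = rolling_codes(codes, k)
        valid = np.flatnonzero(vals >= 0)
        order = valid[np.argsort(vals[valid], kind="stable")]
        sorted_vals = vals[order]
        uniq, first = np.unique(sorted_vals, return_index=True)
        self._uniq = uniq
        self._bounds = np.append(first, sorted_vals.size)
        self._positions = order.astype(np.int64)

    def lookup(self, code: int) -> np.ndarray:
        if code < 0:
            return self._positions[:0]
        i = np.searchsorted(self._uniq, code)
        if i == self._uniq.size or self._uniq[i] != code:
            return self._positions[:0]
        return self._positions[self._bounds[i] : self._bounds[i + 1]]


class ReferenceIndex:
    """Seed index over a set of reference reads for 31 nt queries."""

    def __init__(
        self,
        references: Sequence[Union[ReadRecord, Tuple[str, str]]],
        query_length: int = 31,
    ):
        refs: List[Tuple[str, str]] = []
        for r in references:
            if isinstance(r, ReadRecord):
                refs.append((r.read_id, r.sequence.upper()))
            else:
                refs.append((r[0], r[1].upper()))
        self.ref_ids = [rid for rid, _ in refs]
        self.ref_seqs = [seq for _, seq in refs]
        self.n_refs = len(refs)
        self.query_length = query_length

        sep = np.full(SEPARATOR, 4, dtype=np.uint8)
        chunks = []
        starts = []
        pos = 0
        for _, seq in refs:
            starts.append(pos)
            chunks.append(encode(seq))
            pos += len(seq)
            chunks.append(sep)
            pos += SEPARATOR
        self.concat = (
            np.concatenate(chunks) if chunks else np.zeros(0, dtype=np.uint8)
        )
        self.ref_starts = np.array(starts, dtype=np.int64)
        self.ref_lengths = np.array([len(s) for _, s in refs], dtype=np.int64)
        if self.n_refs and query_length == 31:
            self._k10 = _KmerIndex(self.concat, 10)
            self._k7 = _KmerIndex(self.concat, 7)
            self._k6 = _KmerIndex(self.concat, 6)
        else:
            self._k10 = self._k7 = self._k6 = None

    def ref_of_positions(self, positions: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.ref_starts, positions, side="right") - 1


def _joint_diags(a_pos, a_off, b_pos, b_off, tol: int = 4) -> np.ndarray:
    """Diagonals from seed bucket a that have a supporting seed from bucket b
    on a diagonal within +/- tol (both position arrays are sorted)."""
    if a_pos.size == 0 or b_pos.size == 0:
        return a_pos[:0]
    da = a_pos - a_off
    db = b_pos - b_off
    lo = np.searchsorted(db, da - tol, side="left")
    hi = np.searchsorted(db, da + tol, side="right")
    return da[lo < hi]


def _candidate_diag_refs(index: ReferenceIndex, enc: np.ndarray):
    """All candidate (diagonal, ref) pairs for one 31 nt query orientation."""
    parts_d = []
    parts_p = []
    for off in (0, 10, 20):
        code = _seed_code(enc, off, 10)
        pos = index._k10.lookup(code)
        if pos.size:
            parts_d.append(pos - off)
            parts_p.append(pos)
    for a_off, a_k, b_off, b_k in ((0, 7, 13, 6), (24, 7, 10, 6)):
        a_pos = index._k7.lookup(_seed_code(enc, a_off, a_k))
        b_pos = index._k6.lookup(_seed_code(enc, b_off, b_k))
        d = _joint_diags(a_pos, a_off, b_pos, b_off)
        if d.size:
            parts_d.append(d)
            parts_p.append(d + a_off)
    if not parts_d:
        return None, None
    diags = np.concatenate(parts_d)
    refs = index.ref_of_positions(np.concatenate(parts_p))
    return diags, refs


def _verify_group(
    index: ReferenceIndex,
    enc: np.ndarray,
    ref_idx: int,
    diags: np.ndarray,
    B: int,
    full: int,
    not_bmax: int,
    max_e: int,
) -> Optional[Tuple[int, int, int]]:
    """Best (events, indel_bases, offset) for a query against one reference,
    given candidate diagonals; None if no alignment fits the budgets."""
    concat = index.concat
    ref_start = int(index.ref_starts[ref_idx])
    ref_end = ref_start + int(index.ref_lengths[ref_idx])
    h_min = max_e + 1
    d_best = -1
    for d in diags:
        h = hamming_at(enc, concat, int(d), max_e)
        if h < h_min:
            h_min, d_best = h, int(d)
            if h == 0:
                break
    if h_min == 0:
        return 0, 0, d_best - ref_start
    if h_min == 1:
        # one substitution is already the lexicographic optimum (1, 0)
        return 1, 0, d_best - ref_start
    # need the DP: either no substitution-only alignment fits, or one with
    # h_min events might be beaten by an alignment containing an indel
    max_b = B - 1
    best = -1
    best_w = -1
    cluster: List[int] = []
    sorted_d = sorted(int(d) for d in set(diags.tolist()))
    clusters = []
    for d in sorted_d:
        if cluster and d - cluster[-1] > 3 * max_b:
            clusters.append(cluster)
            cluster = []
        cluster.append(d)
    if cluster:
        clusters.append(cluster)
    n = enc.shape[0]
    for cl in clusters:
        wstart = max(ref_start, cl[0] - max_b)
        wend = min(ref_end, cl[-1] + n + max_b)
        if wend - wstart < n - max_b:
            continue
        k = lattice_dp(enc, concat, wstart, wend - wstart, B, full, not_bmax)
        if k >= 0 and (best < 0 or k < best):
            best, best_w = k, wstart
    if h_min <= max_e and (best < 0 or h_min * B < best):
        best, best_w = h_min * B, d_best
    if best < 0:
        return None
    return best // B, best % B, best_w - ref_start


def _match_encoded(
    index: ReferenceIndex, enc: np.ndarray, params: MatchParams
) -> List[Tuple[int, int, int, int]]:
    """Hits of one query orientation: (ref_idx, events, indel_bases, offset)."""
    B, full, not_bmax = lattice_masks(
        params.max_differences, params.max_total_indel_bases
    )
    max_e = params.max_differences
    hits: List[Tuple[int, int, int, int]] = []
    seeded = (
        index._k10 is not None
        and enc.shape[0] == 31
        and params.max_differences <= 2
        and params.max_total_indel_bases <= 4
    )
    if seeded:
        diags, refs = _candidate_diag_refs(index, enc)
        if diags is None:
            return hits
        order = np.lexsort((diags, refs))
        diags, refs = diags[order], refs[order]
        boundaries = np.flatnonzero(np.diff(refs)) + 1
        for lo, hi in zip(
            np.concatenate(([0], boundaries)),
            np.concatenate((boundaries, [refs.size])),
        ):
            r = int(refs[lo])
            res = _verify_group(
                index, enc, r, diags[lo:hi], B, full, not_bmax, max_e
            )
            if res is not None:
                hits.append((r, res[0], res[1], res[2]))
        return hits
    # exhaustive fallback: verify against every reference window
    if index.n_refs > 20000:
        raise ValueError(
            "exhaustive matching fallback (non-default bounds or query length) "
            "is limited to <= 20000 references"
        )
    n = enc.shape[0]
    for r in range(index.n_refs):
        ref_start = int(index.ref_starts[r])
        wlen = int(index.ref_lengths[r])
        if wlen < n - params.max_total_indel_bases:
            continue
        k = lattice_dp(enc, index.concat, ref_start, wlen, B, full, not_bmax)
        if k >= 0:
            # recover an offset by scanning substitution-only windows first
            off = 0
            for d in range(wlen - n + 1):
                if hamming_at(enc, index.concat, ref_start + d, max_e) == k // B:
                    off = d
                    break
            hits.append((r, k // B, k % B, off))
    return hits


def _rc_encoded(enc: np.ndarray) -> np.ndarray:
    out = np.where(enc > 3, np.uint8(4), (3 - enc).astype(np.uint8))
    return out[::-1]


class Matcher:
    """Caches per-query-sequence match results against one reference index."""

    def __init__(self, index: ReferenceIndex, params: Optional[MatchParams] = None):
        self.index = index
        self.params = params or MatchParams()
        self._cache: Dict[str, List[Tuple[int, int, int, int, int]]] = {}

    def match_sequence(self, seq: str) -> List[Tuple[int, int, int, int, int]]:
        """Hits as (ref_idx, strand, events, indel_bases, offset); strand 0/1
        for +/-. One hit per (reference, strand), reporting the best alignment."""
        seq = seq.upper()
        cached = self._cache.get(seq)
        if cached is not None:
            return cached
        enc = encode(seq)
        hits = [(r, 0, e, b, o) for r, e, b, o in _match_encoded(self.index, enc, self.params)]
        if self.params.search_both_strands:
            rc = _rc_encoded(enc)
            hits += [
                (r, 1, e, b, o)
                for r, e, b, o in _match_encoded(self.index, rc, self.params)
            ]
        self._cache[seq] = hits
        return hits


def match_read(
    query: Union[ReadRecord, str],
    references: Union[ReferenceIndex, Sequence],
    params: Optional[MatchParams] = None,
) -> List[MatchHit]:
    """All reference reads matching the full query within the difference
    bounds; at most one hit per (reference, strand), carrying the best
    alignment's event and indel-base counts."""
    params = params or MatchParams()
    if not isinstance(references, ReferenceIndex):
        references = ReferenceIndex(references)
    if isinstance(query, ReadRecord):
        qid, seq = query.read_id, query.sequence
    else:
        qid, seq = "query", query
    if len(seq) < 12:
        raise ValueError("query too short (< 12 nt) for seeded matching")
    out = []
    for r, s, e, b, o in Matcher(references, params).match_sequence(seq):
        out.append(
            MatchHit(
                query_id=qid,
                reference_id=references.ref_ids[r],
                reference_offset=o,
                strand="+" if s == 0 else "-",
                n_differences=e,
                indel_bases=b,
            )
        )
    return out


def count_hits_per_reference(
    chip_hits: Iterable[Sequence[MatchHit]],
    input_hits: Iterable[Sequence[MatchHit]],
    policy: str = "count_all",
) -> Dict[str, Tuple[float, float]]:
    """Per-reference (chip_count, input_count) under a multi-hit policy.

    ``count_all``: every reference hit by a query gets +1; ``fractional``:
    each query distributes 1 across the distinct references it hits.
    """
    if policy not in ("count_all", "fractional"):
        raise ValueError(f"unknown multi-hit policy: {policy}")
    counts: Dict[str, List[float]] = {}

    def accumulate(hit_lists, slot):
        for hits in hit_lists:
            refs = sorted({h.reference_id for h in hits})
            if not refs:
                continue
            inc = 1.0 if policy == "count_all" else 1.0 / len(refs)
            for rid in refs:
                counts.setdefault(rid, [0.0, 0.0])[slot] += inc

    accumulate(chip_hits, 0)
    accumulate(input_hits, 1)
    return {rid: (c[0], c[1]) for rid, c in counts.items()}


def map_and_count(
    queries: Iterable[ReadRecord],
    matcher: Matcher,
    policy: str = "count_all",
) -> Tuple[np.ndarray, int, int]:
    """Map a read set and accumulate per-reference counts.

    Returns (counts array over reference indices, n_mapped, n_total).
    """
    if policy not in ("count_all", "fractional"):
        raise ValueError(f"unknown multi-hit policy: {policy}")
    counts = np.zeros(matcher.index.n_refs, dtype=np.float64)
    n_mapped = 0
    n_total = 0
    for read in queries:
        n_total += 1
        hits = matcher.match_sequence(read.sequence)
        if not hits:
            continue
        n_mapped += 1
        refs = {h[0] for h in hits}
        inc = 1.0 if policy == "count_all" else 1.0 / len(refs)
        for r in refs:
            counts[r] += inc
    return counts, n_mapped, n_total
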