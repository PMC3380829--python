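"""Characterization of repeat clusters.

For each cluster of reference reads this module assembles a representative
contig by greedy overlap extension, infers the satellite monomer length as
the fundamental period of the contig's self-similarity, verifies
head-to-tail tandem organization (the in-silico analog of outward-facing
primer PCR: at least two adjacent same-orientation consensus copies),
measures AT content, and classifies the cluster as satellite,
LTR-retroelement (by similarity to a provided reference element), or
unclassified.  All-to-all dot-plot matrices expose shared fragments
between families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from Bio import Align

from ._kernels import encode, rolling_codes
from .clustering import overlap_identity
from .records import ReadRecord, reverse_complement


def _rc_enc(enc: np.ndarray) -> np.ndarray:
    return np.where(enc > 3, np.uint8(4), (3 - enc).astype(np.uint8))[::-1]


def _decode(enc: np.ndarray) -> str:
    return bytes(b"ACGTN"[c] for c in enc).decode()


# ---------------------------------------------------------------------------
# representative contig
# ---------------------------------------------------------------------------


@dataclass
class Contig:
    sequence: str
    n_reads_used: int
    low_confidence: bool = False


class _ReadOverlapIndex:
    """K-mer index over both orientations of a cluster's reads."""

    def __init__(self, enc_reads: List[np.ndarray], read_ids: List[str], kmer: int):
        self.kmer = kmer
        self.read_ids = read_ids
        self.oriented: Dict[Tuple[int, int], np.ndarray] = {}
        self.buckets: Dict[int, List[Tuple[int, int, int]]] = {}
        for idx, enc in enumerate(enc_reads):
            for orient, arr in ((0, enc), (1, _rc_enc(enc))):
                self.oriented[(idx, orient)] = arr
                codes = rolling_codes(arr, kmer)
                for p in range(codes.shape[0]):
                    v = int(codes[p])
                    if v >= 0:
                        self.buckets.setdefault(v, []).append((idx, orient, p))


def _extension_candidates(
    contig: np.ndarray,
    index: _ReadOverlapIndex,
    min_overlap: int,
    min_identity: float,
):
    """All reads usably extending the contig 3' end:
    (extension_length, read_id, appended_array) per candidate."""
    tail_len = min(contig.shape[0], 150)
    tail = contig[-tail_len:]
    tail_codes = rolling_codes(tail, index.kmer)
    diags: Dict[Tuple[int, int], set] = {}
    for p in range(tail_codes.shape[0]):
        v = int(tail_codes[p])
        if v < 0:
            continue
        for idx, orient, rp in index.buckets.get(v, ()):
            diags.setdefault((idx, orient), set()).add(p - rp)
    out = []
    for (idx, orient), dset in diags.items():
        r = index.oriented[(idx, orient)]
        for d in sorted(dset):
            ext = (d + r.shape[0]) - tail_len
            if ext < 5:
                continue
            a_lo, a_hi = max(0, d), min(tail_len, r.shape[0] + d)
            ov = a_hi - a_lo
            if ov < min_overlap:
                continue
            ident = float(
                np.count_nonzero(tail[a_lo:a_hi] == r[a_lo - d : a_hi - d])
            ) / ov
            if ident < min_identity:
                continue
            out.append((ext, index.read_ids[idx], idx, r[tail_len - d :]))
    return out


def _choose_extension(candidates) -> Optional[np.ndarray]:
    """Longest extension whose first bases are confirmed by a second read.

    Cluster reads tile the repeat at substantial depth, so a genuine
    extension is corroborated by other reads; sequence that only a single
    read can provide (e.g. unique flanking sequence carried by an
    array-junction read) is a dead end for the walk and is deferred.
    """
    if not candidates:
        return None

    def supported(cand):
        ext, rid, idx, app = cand
        probe = app[: min(20, app.shape[0])]
        for ext2, rid2, idx2, app2 in candidates:
            if idx2 == idx:
                continue
            n = min(probe.shape[0], app2.shape[0])
            if n < 10:
                continue
            matches = int(np.count_nonzero(probe[:n] == app2[:n]))
            if matches >= 0.8 * n:
                return True
        return False

    pool = [c for c in candidates if supported(c)] or list(candidates)
    pool.sort(key=lambda c: (-c[0], c[1]))
    return pool[0][3]


def assemble_representative(
    reads: Sequence[ReadRecord],
    kmer: int = 13,
    min_overlap: int = 30,
    min_identity: float = 0.85,
    max_length: int = 4600,
    max_restarts: int = 3,
) -> Contig:
    """Greedy overlap-consensus contig for a cluster.

    The longest read (ties broken by read id) seeds the contig, which is
    extended greedily at both ends by overlapping cluster reads (either
    orientation, reads reusable), preferring extensions corroborated by a
    second read so the walk does not wander into unique flanking sequence.
    Tandem arrays therefore yield contigs that circle the monomer until
    ``max_length``.  If a walk still stalls early (a dead end at an array
    junction), it is restarted from other seed reads and the longest
    contig wins.  A cluster with no usable overlaps degenerates to its
    longest read, flagged low-confidence.
    """
    if not reads:
        raise ValueError("cannot assemble an empty cluster")
    ordered = sorted(reads, key=lambda r: (-len(r.sequence), r.read_id))
    if len(reads) == 1:
        return Contig(ordered[0].sequence, 1, low_confidence=True)
    enc_reads = [encode(r.sequence) for r in ordered]
    read_ids = [r.read_id for r in ordered]
    index = _ReadOverlapIndex(enc_reads, read_ids, kmer)

    def walk(seed_idx: int) -> Tuple[np.ndarray, int, bool]:
        contig = enc_reads[seed_idx]
        used = 1
        extended = False
        for _ in range(2):  # forward pass, then the mirrored (5') pass
            while contig.shape[0] < max_length:
                cands = _extension_candidates(contig, index, min_overlap, min_identity)
                ext = _choose_extension(cands)
                if ext is None or ext.shape[0] == 0:
                    break
                contig = np.concatenate([contig, ext])
                used += 1
                extended = True
            contig = _rc_enc(contig)
        return contig, used, extended

    n = len(ordered)
    seeds = [0] + [(k * n) // (max_restarts + 1) for k in range(1, max_restarts + 1)]
    seen = set()
    best: Optional[Tuple[np.ndarray, int, bool]] = None
    for seed_idx in seeds:
        if seed_idx in seen:
            continue
        seen.add(seed_idx)
        result = walk(seed_idx)
        if best is None or result[0].shape[0] > best[0].shape[0]:
            best = result
        if best[0].shape[0] >= 0.6 * max_length:
            break
    contig, used, extended = best
    return Contig(_decode(contig), used, low_confidence=not extended)


# ---------------------------------------------------------------------------
# monomer periodicity
# ---------------------------------------------------------------------------


def self_identity_curve(seq: Union[str, np.ndarray], max_shift: Optional[int] = None) -> np.ndarray:
    """identity(s) between the sequence and itself shifted by s = 1..max_shift."""
    arr = encode(seq) if isinstance(seq, str) else seq
    L = arr.shape[0]
    if max_shift is None:
        max_shift = L // 2
    out = np.zeros(max_shift + 1)
    for s in range(1, max_shift + 1):
        if L - s <= 0:
            break
        out[s] = np.count_nonzero(arr[: L - s] == arr[s:]) / (L - s)
    return out


def periodic_core(seq: str, period: int, min_support: float = 0.6) -> Tuple[int, int]:
    """[start, end) of the longest region of the sequence that actually
    repeats with the given period.

    Representative contigs of satellite clusters can carry short
    non-repetitive tails (flanking sequence brought in by junction reads);
    positions x are scored by whether seq[x] == seq[x + period], smoothed
    over a window, and the widest supported run (extended by one period)
    is returned.  Falls back to the whole sequence when it is too short to
    judge.
    """
    arr = encode(seq)
    L = arr.shape[0]
    if period < 1 or L < 2 * period:
        return 0, L
    eq = (arr[: L - period] == arr[period:]).astype(np.float64)
    w = int(min(50, period))
    kernel = np.ones(w) / w
    smooth = np.convolve(eq, kernel, mode="valid")
    good = np.flatnonzero(smooth >= min_support)
    if good.size == 0:
        return 0, L
    start = int(good[0])
    end = int(good[-1]) + w + period
    return start, min(end, L)


def estimate_monomer_length(
    seq: str, min_identity: float = 0.8, min_overlap: int = 25
) -> Tuple[Optional[int], float]:
    """Fundamental period: the smallest shift whose self-identity reaches
    ``min_identity`` (so a dimer array still reports the monomer).  Returns
    (None, best identity seen) for aperiodic sequences.  Shifts leaving
    fewer than ``min_overlap`` comparable bases are not trusted; the floor
    is deliberately low so that a contig only slightly longer than one
    period (a tiling-gap-limited assembly of a long monomer) still yields
    its period."""
    arr = encode(seq)
    L = arr.shape[0]
    effective_overlap = min(min_overlap, max(1, L // 2))
    max_shift = L - effective_overlap
    if L < 2 or max_shift < 1:
        return None, 0.0
    curve = self_identity_curve(arr, min(max_shift, L - 1))
    for s in range(1, curve.shape[0]):
        if curve[s] >= min_identity:
            return s, float(curve[s])
    return None, float(curve[1:].max(initial=0.0))


# ---------------------------------------------------------------------------
# tandem organization
# ---------------------------------------------------------------------------


@dataclass
class TandemCheck:
    head_to_tail: bool
    n_copies: int


def _occurrences(
    target: np.ndarray, probe: np.ndarray, kmer: int, min_identity: float
) -> List[int]:
    """Approximate start positions of probe in target (one orientation),
    anchored on shared k-mers and scored ungapped."""
    m = probe.shape[0]
    probe_pos: Dict[int, int] = {}
    codes = rolling_codes(probe, kmer)
    for p in range(codes.shape[0]):
        v = int(codes[p])
        if v >= 0 and v not in probe_pos:
            probe_pos[v] = p
    support: Dict[int, int] = {}
    tcodes = rolling_codes(target, kmer)
    for p in range(tcodes.shape[0]):
        v = int(tcodes[p])
        if v >= 0 and v in probe_pos:
            d = p - probe_pos[v]
            support[d] = support.get(d, 0) + 1
    hits = []
    for d in sorted(support):
        if support[d] < 2:
            continue
        lo = max(0, d)
        hi = min(target.shape[0], d + m)
        if hi - lo < 0.8 * m:
            continue
        ident = float(
            np.count_nonzero(target[lo:hi] == probe[lo - d : hi - d])
        ) / (hi - lo)
        if ident >= min_identity:
            hits.append(d)
    # merge anchors closer than half a monomer (same occurrence)
    merged: List[int] = []
    for d in hits:
        if merged and d - merged[-1] < m // 2:
            continue
        merged.append(d)
    return merged


def verify_tandem_organization(
    sequence: str,
    consensus: str,
    min_identity: float = 0.7,
    max_gap_fraction: float = 0.1,
    kmer: int = 13,
) -> TandemCheck:
    """True iff the sequence contains >= 2 adjacent same-orientation copies
    of the consensus with inter-copy gap <= max_gap_fraction * monomer."""
    target = encode(sequence)
    m = len(consensus)
    n_total = 0
    head_to_tail = False
    for probe in (encode(consensus), _rc_enc(encode(consensus))):
        occ = _occurrences(target, probe, min(kmer, max(6, m // 4)), min_identity)
        n_total += len(occ)
        for a, b in zip(occ, occ[1:]):
            gap = (b - a) - m
            if abs(gap) <= max_gap_fraction * m:
                head_to_tail = True
    return TandemCheck(head_to_tail=head_to_tail, n_copies=n_total)


# ---------------------------------------------------------------------------
# composition and classification
# ---------------------------------------------------------------------------


def at_content(sequence: str) -> Optional[float]:
    """(A+T) fraction over unambiguous bases; None if no unambiguous base."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    informative = sum(counts.values())
    if informative == 0:
        return None
    return (counts["A"] + counts["T"]) / informative


def library_similarity(
    contig: str, library: Sequence[Tuple[str, str]], kmer: int = 13
) -> Tuple[float, float, Optional[str]]:
    """Best (identity, coverage of contig, library id) of the contig against
    a reference element library, on the best shared-k-mer diagonal, both
    strands."""
    enc_c = encode(contig)
    best = (0.0, 0.0, None)
    for name, seq in library:
        for enc_l in (encode(seq), _rc_enc(encode(seq))):
            codes_l = rolling_codes(enc_l, kmer)
            lib_pos: Dict[int, int] = {}
            for p in range(codes_l.shape[0]):
                v = int(codes_l[p])
                if v >= 0 and v not in lib_pos:
                    lib_pos[v] = p
            diags = set()
            codes_c = rolling_codes(enc_c, kmer)
            for p in range(codes_c.shape[0]):
                v = int(codes_c[p])
                if v >= 0 and v in lib_pos:
                    diags.add(p - lib_pos[v])
            if not diags:
                continue
            ident, ov = overlap_identity(enc_c, enc_l, sorted(diags), 1)
            cov = ov / enc_c.shape[0]
            if (ident, cov) > (best[0], best[1]):
                best = (ident, cov, name)
    return best


def classify_cluster(
    contig: str,
    monomer_length: Optional[int],
    head_to_tail: bool,
    retro_library: Sequence[Tuple[str, str]] = (),
    min_retro_identity: float = 0.8,
    min_retro_coverage: float = 0.5,
) -> Tuple[str, str]:
    """(classification, flags): satellite iff periodic AND head-to-tail;
    ltr_retroelement iff sufficiently similar to a library element (winning
    over a conflicting satellite signal, flagged)."""
    retro_similar = False
    if retro_library:
        ident, cov, _ = library_similarity(contig, retro_library)
        retro_similar = ident >= min_retro_identity and cov >= min_retro_coverage
    satellite = monomer_length is not None and head_to_tail
    if retro_similar and satellite:
        return "ltr_retroelement", "conflict:periodic_and_retro_similar"
    if retro_similar:
        return "ltr_retroelement", ""
    if satellite:
        return "satellite", ""
    return "unclassified", ""


# ---------------------------------------------------------------------------
# dot plots
# ---------------------------------------------------------------------------


@dataclass
class DotplotMatrix:
    sequence_ids: List[str]
    window: int
    min_identity: float
    matches: List[Tuple[str, int, str, int, str]] = field(default_factory=list)


def dotplot(
    sequences: Sequence[Tuple[str, str]],
    window: int = 50,
    min_identity: float = 0.9,
) -> DotplotMatrix:
    """Windowed match coordinates for all ordered pairs (including
    self-pairs), both strands.  A match (a, i, b, j, strand) means
    a[i:i+w] aligns to b[j:j+w] (forward frame of b for '+'; for '-' the
    window matches the reverse complement of b and j indexes b's forward
    frame) at >= min_identity."""
    ids = [name for name, _ in sequences]
    if sequences and window > min(len(s) for _, s in sequences):
        raise ValueError("window exceeds the shortest sequence")
    enc = {name: encode(seq) for name, seq in sequences}
    out = DotplotMatrix(sequence_ids=ids, window=window, min_identity=min_identity)
    need = int(np.ceil(min_identity * window))
    for name_a, _ in sequences:
        a = enc[name_a]
        la = a.shape[0]
        for name_b, _ in sequences:
            for strand in "+-":
                b = enc[name_b] if strand == "+" else _rc_enc(enc[name_b])
                lb = b.shape[0]
                for d in range(-(lb - window), la - window + 1):
                    lo = max(0, d)
                    hi = min(la, lb + d)
                    if hi - lo < window:
                        continue
                    eq = (a[lo:hi] == b[lo - d : hi - d]).astype(np.int32)
                    sums = np.convolve(eq, np.ones(window, dtype=np.int32), "valid")
                    for t in np.flatnonzero(sums >= need):
                        i = lo + int(t)
                        j_rc = i - d
                        j = j_rc if strand == "+" else lb - j_rc - window
                        out.matches.append((name_a, i, name_b, int(j), strand))
    return out


# ---------------------------------------------------------------------------
# pairwise identity
# ---------------------------------------------------------------------------


def pairwise_identity(
    seq_a: str, seq_b: str, alphabet: str = "nucleotide"
) -> float:
    """Percent identity from an end-gap-free global alignment
    (match +1, mismatch -1, gap open -2, gap extend -0.5): matches divided
    by alignment columns between the first and last aligned pair."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5
    aligner.target_end_gap_score = 0
    aligner.query_end_gap_score = 0
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        return 0.0
    matches = 0
    aligned = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        aligned += a1 - a0
        for x, y in zip(seq_a.upper()[a0:a1], seq_b.upper()[b0:b1]):
            if x == y:
                matches += 1
    span_a = int(blocks_a[-1][1] - blocks_a[0][0])
    span_b = int(blocks_b[-1][1] - blocks_b[0][0])
    columns = aligned + (span_a - aligned) + (span_b - aligned)
    return 100.0 * matches / columns
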