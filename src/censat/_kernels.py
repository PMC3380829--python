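"""Numba kernels for bounded-difference read matching.

The difference model: a query matches a reference window if there is an
alignment (global in the query, local in the reference) with at most
``max_e`` difference *events*, where a mismatch is one event and a
contiguous indel run of L bases is one event contributing L bases to a
separate budget of ``max_b`` total indel bases.

The verifier is a banded dynamic program over a bitmask lattice: each DP
cell holds a bitmask over (events e, indel bases b) states, k = e*B + b
with B = max_b + 1.  Advancing by a mismatch shifts the mask by B (e+1),
opening an indel shifts by B+1 (e+1, b+1), extending an indel shifts by 1
(b+1, same e).  Base code 4 (N) never matches anything, which also makes
the N-run separators between concatenated reference reads impassable.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _ENC[_c] = _i
    _ENC[ord(chr(_c).lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode A/C/G/T to 0..3, anything else (incl. N) to 4."""
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def lattice_masks(max_e: int, max_b: int):
    """Constants for the (events, indel-bases) bitmask lattice."""
    B = max_b + 1
    E = max_e + 1
    nbits = E * B
    if nbits > 60:
        raise ValueError("difference bounds too large for the bitmask verifier")
    full = (1 << nbits) - 1
    not_bmax = 0
    for k in range(nbits):
        if k % B != B - 1:
            not_bmax |= 1 << k
    return B, full, not_bmax


@njit(cache=True)
def hamming_at(q, ref, start, limit):
    """Mismatch count of q against ref[start:start+len(q)] (N mismatches
    everything); returns limit+1 early once the limit is exceeded or the
    window leaves the array."""
    n = q.shape[0]
    if start < 0 or start + n > ref.shape[0]:
        return limit + 1
    h = 0
    for i in range(n):
        a = q[i]
        r = ref[start + i]
        if a != r or a == 4:
            h += 1
            if h > limit:
                return h
    return h


@njit(cache=True)
def lattice_dp(q, ref, wstart, wlen, B, full, not_bmax):
    """Best (events, indel bases) for aligning the full query within
    ref[wstart:wstart+wlen], free at both reference ends.

    Returns the packed state k = e*B + b of the best alignment
    (lexicographic minimum over (e, b)), or -1 if none fits the budgets.
    """
    n = q.shape[0]
    W = wlen
    shift_mm = B
    shift_open = B + 1
    M = np.zeros(W + 1, dtype=np.int64)
    I = np.zeros(W + 1, dtype=np.int64)
    D = np.zeros(W + 1, dtype=np.int64)
    for j in range(W + 1):
        M[j] = 1  # free start anywhere in the window
    newM = np.zeros(W + 1, dtype=np.int64)
    newI = np.zeros(W + 1, dtype=np.int64)
    newD = np.zeros(W + 1, dtype=np.int64)
    for i in range(n):
        qc = q[i]
        for j in range(W + 1):
            newM[j] = 0
            newI[j] = 0
            newD[j] = 0
        for j in range(W):
            src = M[j] | I[j] | D[j]
            if src != 0:
                rc = ref[wstart + j]
                if qc == rc and qc != 4:
                    newM[j + 1] |= src
                else:
                    newM[j + 1] |= (src << shift_mm) & full
        for j in range(W + 1):
            open_src = (M[j] | D[j]) & not_bmax
            ext_src = I[j] & not_bmax
            newI[j] |= ((open_src << shift_open) & full) | (ext_src << 1)
        for j in range(W):
            src = (newM[j] | newI[j]) & not_bmax
            newD[j + 1] |= (src << shift_open) & full
            newD[j + 1] |= (newD[j] & not_bmax) << 1
        for j in range(W + 1):
            M[j] = newM[j]
            I[j] = newI[j]
            D[j] = newD[j]
    acc = np.int64(0)
    for j in range(W + 1):
        acc |= M[j] | I[j]  # trailing deletions are dominated; drop D
    if acc == 0:
        return -1
    k = 0
    while acc & (1 << k) == 0:
        k += 1
    return k


@njit(cache=True)
def rolling_codes(codes, k):
    """Little-endian 2-bit rolling k-mer codes; windows containing a
    non-ACGT base get code -1."""
    n = codes.shape[0]
    m = n - k + 1
    out = np.empty(m, dtype=np.int64)
    if m <= 0:
        return out[:0]
    for i in range(m):
        v = np.int64(0)
        ok = True
        for j in range(k):
            c = codes[i + j]
            if c > 3:
                ok = False
                break
            v |= np.int64(c) << (2 * j)
        out[i] = v if ok else -1
    return out
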