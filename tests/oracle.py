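"""Independent brute-force oracles used by the test suite.

These enumerate alignments directly from the difference-model definition
(states over query position, reference position, events, indel bases,
last-operation), with none of the seeding or banding machinery of the
production matcher.
"""

from __future__ import annotations

from typing import Optional, Tuple

ACGT = set("ACGT")
_NONE, _INS, _DEL = 0, 1, 2


def oracle_best_alignment(
    query: str, ref: str, max_e: int = 2, max_b: int = 4
) -> Optional[Tuple[int, int]]:
    """Lexicographically minimal (events, indel_bases) over every alignment
    of the full query to any window of ref, or None if no alignment fits.

    A mismatch is one event; a contiguous indel run of L bases is one event
    contributing L to the indel-base budget.  N never matches anything.
    """
    n, m = len(query), len(ref)
    # reachable[(j, last)] = set of (events, indel_bases) after consuming
    # i query chars and ending at reference position j
    cur = {}
    for j in range(m + 1):
        cur[(j, _NONE)] = {(0, 0)}
    for i in range(n):
        nxt: dict = {}

        def add(key, eb):
            nxt.setdefault(key, set()).add(eb)

        qc = query[i]
        for (j, last), ebs in cur.items():
            for e, b in ebs:
                if j < m:
                    rc = ref[j]
                    cost = 0 if (qc == rc and qc in ACGT) else 1
                    if e + cost <= max_e:
                        add((j + 1, _NONE), (e + cost, b))
                # insertion: consume the query char, merge adjacent runs
                e2 = e + 1 if last != _INS else e
                if e2 <= max_e and b + 1 <= max_b:
                    add((j, _INS), (e2, b + 1))
        # deletions consume reference only; sweep left to right
        for j in range(m):
            for last in (_NONE, _INS, _DEL):
                for e, b in set(nxt.get((j, last), ())):
                    if last == _DEL:
                        if b + 1 <= max_b:
                            add((j + 1, _DEL), (e, b + 1))
                    elif e + 1 <= max_e and b + 1 <= max_b:
                        add((j + 1, _DEL), (e + 1, b + 1))
        cur = nxt
    best = None
    for (_, last), ebs in cur.items():
        for eb in ebs:
            if best is None or eb < best:
                best = eb
    return best


def brute_force_min_period(seq: str) -> int:
    """Smallest p >= 1 with seq[i] == seq[i + p] for all valid i."""
    n = len(seq)
    for p in range(1, n + 1):
        if all(seq[i] == seq[i + p] for i in range(n - p)):
            return p
    return n
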