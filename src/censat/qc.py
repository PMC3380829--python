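"""Read trimming and quality filtering of ChIP/input reads.

Reads are trimmed at both the 5' and 3' ends to a fixed target length
(36 nt -> 31 nt by default) and then discarded if they contain more than
``max_low_quality_bases`` bases below the Phred threshold (Q20 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional

import numpy as np

from .records import ReadRecord


@dataclass(frozen=True)
class QCParams:
    target_length: int = 31
    trim_5p: int = 3
    trim_3p: int = 2
    quality_threshold: int = 20
    max_low_quality_bases: int = 1

    def __post_init__(self) -> None:
        if min(self.target_length, self.trim_5p, self.trim_3p) < 0:
            raise ValueError("lengths and trim amounts must be non-negative")
        if self.quality_threshold < 0 or self.max_low_quality_bases < 0:
            raise ValueError("thresholds must be non-negative")

    @classmethod
    def for_read_length(cls, read_length: int, target_length: int = 31) -> "QCParams":
        """Default trim split for a given input read length: the excess is
        removed preferentially from the 5' end (3'-biased splits are
        equivalent downstream; the split is configurable)."""
        excess = read_length - target_length
        if excess < 0:
            raise ValueError("read_length shorter than target_length")
        return cls(target_length=target_length, trim_5p=-(-excess // 2), trim_3p=excess // 2)


def trim_read(read: ReadRecord, params: QCParams) -> Optional[ReadRecord]:
    """Trim to target length; returns None for reads too short to trim."""
    needed = params.trim_5p + params.target_length + params.trim_3p
    if len(read.sequence) < needed:
        return None
    s, e = params.trim_5p, params.trim_5p + params.target_length
    quals = read.qualities
    return ReadRecord(
        read_id=read.read_id,
        sequence=read.sequence[s:e],
        qualities=None if quals is None else quals[s:e],
        truth_family=read.truth_family,
    )


def quality_filter(read: ReadRecord, params: QCParams) -> bool:
    """Keep iff at most ``max_low_quality_bases`` bases fall below the
    quality threshold."""
    if read.qualities is None:
        raise ValueError(f"read {read.read_id}: quality filtering requires FASTQ qualities")
    low = int(np.count_nonzero(np.asarray(read.qualities) < params.quality_threshold))
    return low <= params.max_low_quality_bases


@dataclass
class QCResult:
    reads: List[ReadRecord]
    n_input: int
    n_dropped_short: int
    n_dropped_quality: int

    @property
    def n_surviving(self) -> int:
        return len(self.reads)


def run_qc(reads: Iterable[ReadRecord], params: Optional[QCParams] = None) -> QCResult:
    """Trim then quality-filter a read set, keeping per-reason drop counts."""
    params = params or QCParams()
    surviving: List[ReadRecord] = []
    n_in = n_short = n_qual = 0
    for read in reads:
        n_in += 1
        trimmed = trim_read(read, params)
        if trimmed is None:
            n_short += 1
            continue
        if not quality_filter(trimmed, params):
            n_qual += 1
            continue
        surviving.append(trimmed)
    return QCResult(surviving, n_in, n_short, n_qual)
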