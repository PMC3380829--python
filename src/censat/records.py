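"""Core record types shared across the pipeline.

A :class:`ReadRecord` is the universal currency: 36 nt ChIP/input reads
carry Phred qualities, 100 nt genomic reference reads usually do not.
Synthetic reads additionally carry a ``truth_family`` label recording the
repeat family (or ``"background"``) they were sampled from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class ReadRecord:
    """A sequencing read, optionally with Phred qualities and truth label."""

    read_id: str
    sequence: str
    qualities: Optional[Sequence[int]] = None
    truth_family: Optional[str] = None

    def __post_init__(self) -> None:
        if self.qualities is not None:
            if len(self.qualities) != len(self.sequence):
                raise ValueError(
                    f"read {self.read_id}: {len(self.qualities)} qualities "
                    f"for {len(self.sequence)} bases"
                )
            q = self.qualities
            lo, hi = (q.min(), q.max()) if hasattr(q, "min") else (min(q), max(q))
            if len(q) and (lo < 0 or hi > 60):
                raise ValueError(f"read {self.read_id}: Phred scores must be in [0, 60]")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MatchHit:
    """An approximate alignment of a full query read to a reference read.

    ``n_differences`` counts difference *events* (a mismatch is one event,
    an indel run of L bases is one event contributing L to ``indel_bases``).
    """

    query_id: str
    reference_id: str
    reference_offset: int
    strand: str
    n_differences: int
    indel_bases: int


@dataclass
class RepeatCluster:
    """A connected component of mutually similar reference reads."""

    cluster_id: str
    member_ids: list
    genome_proportion: float
    chip_count: float = 0.0
    input_count: float = 0.0
    enrichment: Optional[float] = None
    classification: str = "unclassified"

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class FamilyReport:
    """One row of the family summary table (Table-1-style)."""

    family_id: str
    classification: str
    enrichment: float
    genome_proportion_pct: float
    total_mbp: float
    monomer_length: Optional[int]
    at_content: Optional[float]
    n_reads: int = 0
    chip_count: float = 0.0
    input_count: float = 0.0
    flags: str = ""
    localization: str = ""
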