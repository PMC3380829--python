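"""Truth-annotated synthetic genomes and simulated read sets.

The generator emulates the repeat landscape the analysis assumes: a large
AT-rich genome carrying many tandem-satellite families of widely different
monomer length, one dispersed LTR-retroelement family, low-coverage (<<1x)
genomic reference reads, and ChIP/input read pairs in which reads are
sampled with a per-position weight proportional to the fold-enrichment of
the repeat family covering the position (background weight 1).

With family genome fractions ``p_g`` and sampling weights ``f_g`` the
expected realized ChIP/input enrichment of family ``f`` is

    E_f = f_f / sum_g p_g * f_g

(the denominator renormalizes ChIP sampling to a probability), so strongly
enriched families realize E well below their nominal weight whenever
enriched repeats occupy a non-negligible genome fraction -- the same effect
that makes most repeats look ChIP-depleted in real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .records import ReadRecord, reverse_complement

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SatelliteFamilySpec:
    """A tandem-satellite family: head-to-tail copies of one consensus monomer."""

    family_id: str
    monomer_length: int
    at_content: float
    n_loci: int
    copies_per_locus: Tuple[int, int]
    divergence: float = 0.0
    fold_enrichment: float = 1.0

    def __post_init__(self) -> None:
        if self.monomer_length < 1:
            raise ValueError("monomer_length must be >= 1")
        if not 0.0 <= self.at_content <= 1.0:
            raise ValueError("at_content must be in [0, 1]")
        if not 0.0 <= self.divergence <= 0.3:
            raise ValueError("divergence must be in [0, 0.3]")
        if self.fold_enrichment < 0:
            raise ValueError("fold_enrichment must be >= 0")
        lo, hi = self.copies_per_locus
        if lo < 1 or hi < lo:
            raise ValueError("copies_per_locus must be a valid positive range")


@dataclass(frozen=True)
class RetroelementSpec:
    """A dispersed (non-tandem) LTR-retroelement family."""

    family_id: str
    element_length: int
    n_insertions: int
    divergence: float = 0.0
    fold_enrichment: float = 1.0
    at_content: float = 0.62

    def __post_init__(self) -> None:
        if self.element_length < 1 or self.n_insertions < 1:
            raise ValueError("element_length and n_insertions must be >= 1")
        if self.fold_enrichment < 0:
            raise ValueError("fold_enrichment must be >= 0")


RepeatSpec = Union[SatelliteFamilySpec, RetroelementSpec]


@dataclass
class SyntheticGenome:
    """A nucleotide sequence plus truth annotations of every repeat copy region.

    Annotations are (family_id, start, end, strand), 0-based half-open,
    one interval per satellite locus / retroelement insertion; they never
    overlap and always lie within the sequence.
    """

    sequence: str
    annotations: List[Tuple[str, int, int, str]]
    genome_size_mbp: float
    consensi: Dict[str, str] = field(default_factory=dict)
    family_folds: Dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequence)

    def family_bp(self) -> Dict[str, int]:
        bp: Dict[str, int] = {}
        for fam, s, e, _ in self.annotations:
            bp[fam] = bp.get(fam, 0) + (e - s)
        return bp

    def family_proportions(self) -> Dict[str, float]:
        n = len(self.sequence)
        return {fam: bp / n for fam, bp in self.family_bp().items()}


def random_consensus(length: int, at_content: float, rng: np.random.Generator) -> str:
    """Random consensus whose realized A+T count is exactly round(at * length)."""
    n_at = int(round(at_content * length))
    at = rng.integers(0, 2, size=n_at)  # 0 -> A, 1 -> T
    gc = rng.integers(0, 2, size=length - n_at)  # 0 -> C, 1 -> G
    arr = np.concatenate([np.where(at == 0, 65, 84), np.where(gc == 0, 67, 71)])
    rng.shuffle(arr)
    return arr.astype(np.uint8).tobytes().decode()


def mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Independent per-base substitutions at the given probability.

    Replacement bases are drawn from the sequence's own base composition
    (redrawn while equal to the original), so divergence leaves the AT
    content of repeat copies unbiased -- substitution patterns in AT-rich
    satellites preserve their skewed composition rather than eroding it
    toward 50%.
    """
    if divergence <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    counts = np.array([(arr == b).sum() for b in BASES], dtype=float)
    if counts.sum() == 0:
        return seq
    comp = counts / counts.sum()
    hit = rng.random(arr.size) < divergence
    idx = np.flatnonzero(hit)
    if idx.size:
        cur = arr[idx]
        repl = BASES[rng.choice(4, size=idx.size, p=comp)]
        same = repl == cur
        while np.any(same):
            repl[same] = BASES[rng.choice(4, size=int(same.sum()), p=comp)]
            same = repl == cur
        arr[idx] = repl
    return arr.tobytes().decode()


def _realize_segments(
    specs: Sequence[RepeatSpec],
    consensi: Dict[str, str],
    rng: np.random.Generator,
) -> List[Tuple[str, str]]:
    """Expand specs into concrete (family_id, segment_sequence) repeat blocks."""
    segments: List[Tuple[str, str]] = []
    for spec in specs:
        cons = consensi[spec.family_id]
        if isinstance(spec, SatelliteFamilySpec):
            lo, hi = spec.copies_per_locus
            for _ in range(spec.n_loci):
                n_copies = int(rng.integers(lo, hi + 1))
                array = "".join(
                    mutate(cons, spec.divergence, rng) for _ in range(n_copies)
                )
                segments.append((spec.family_id, array))
        else:
            for _ in range(spec.n_insertions):
                segments.append((spec.family_id, mutate(cons, spec.divergence, rng)))
    return segments


def build_genome(
    specs: Sequence[RepeatSpec],
    background_length: int,
    seed: int,
    genome_size_mbp: Optional[float] = None,
    background_at: float = 0.62,
    min_separation: int = 200,
) -> SyntheticGenome:
    """Assemble repeat segments into a random background sequence.

    Each satellite family contributes ``n_loci`` tandem arrays; the
    retroelement contributes dispersed single-copy insertions.  Insertion
    points are distinct and separated by at least ``min_separation`` bp of
    background, so annotations never overlap and arrays of the same family
    never fuse.  The genome length is exactly ``background_length`` plus the
    total repeat length.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    ids = [s.family_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("family_id values must be unique")
    rng = np.random.default_rng(seed)
    consensi = {
        s.family_id: random_consensus(
            s.monomer_length if isinstance(s, SatelliteFamilySpec) else s.element_length,
            s.at_content,
            rng,
        )
        for s in specs
    }
    segments = _realize_segments(specs, consensi, rng)
    total_repeat = sum(len(seg) for _, seg in segments)
    if background_length <= total_repeat:
        raise ValueError(
            f"cannot place {total_repeat} bp of repeats at requested density: "
            f"background_length ({background_length}) must exceed total repeat length"
        )
    n_seg = len(segments)
    if (n_seg + 1) * min_separation >= background_length:
        raise ValueError(
            f"cannot place {n_seg} repeat segments with {min_separation} bp "
            f"separation in {background_length} bp of background"
        )
    order = rng.permutation(n_seg)
    segments = [segments[i] for i in order]

    # distinct insertion points with minimum separation: sample from the
    # shrunken space then re-inflate
    slack = background_length - (n_seg + 1) * min_separation
    points = np.sort(rng.choice(slack, size=n_seg, replace=False))
    points = points + min_separation * (1 + np.arange(n_seg))

    background = random_consensus(background_length, background_at, rng)
    parts: List[str] = []
    annotations: List[Tuple[str, int, int, str]] = []
    prev = 0
    out_pos = 0
    for (fam, seg), point in zip(segments, points):
        parts.append(background[prev:point])
        out_pos += point - prev
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        placed = seg if strand == "+" else reverse_complement(seg)
        parts.append(placed)
        annotations.append((fam, out_pos, out_pos + len(seg), strand))
        out_pos += len(seg)
        prev = point
    parts.append(background[prev:])
    sequence = "".join(parts)
    assert len(sequence) == background_length + total_repeat

    if genome_size_mbp is None:
        genome_size_mbp = len(sequence) / 1e6
    return SyntheticGenome(
        sequence=sequence,
        annotations=annotations,
        genome_size_mbp=genome_size_mbp,
        consensi=consensi,
        family_folds={s.family_id: s.fold_enrichment for s in specs},
    )


class _TruthLabeller:
    """Majority-bp truth labelling of reads against genome annotations."""

    def __init__(self, genome: SyntheticGenome):
        self.starts = np.array([a[1] for a in genome.annotations], dtype=np.int64)
        self.ends = np.array([a[2] for a in genome.annotations], dtype=np.int64)
        self.fams = [a[0] for a in genome.annotations]

    def label(self, start: int, end: int) -> str:
        lo = int(np.searchsorted(self.ends, start, side="right"))
        hi = int(np.searchsorted(self.starts, end, side="left"))
        length = end - start
        best_fam, best_bp = "background", 0
        covered = 0
        for k in range(lo, hi):
            ov = min(end, int(self.ends[k])) - max(start, int(self.starts[k]))
            if ov > 0:
                covered += ov
                if ov > best_bp:
                    best_fam, best_bp = self.fams[k], ov
        background_bp = length - covered
        # majority-bp rule; ties (including vs background) -> background
        return best_fam if best_bp > background_bp else "background"


def simulate_reference_reads(
    genome: SyntheticGenome,
    coverage: float,
    read_length: int = 100,
    seed: int = 0,
) -> List[ReadRecord]:
    """Uniform low-coverage genomic reads; minus-strand reads are
    reverse-complemented. Read count = round(coverage * genome_length / read_length)."""
    if not 0 < coverage <= 2:
        raise ValueError("coverage must be in (0, 2]")
    n = len(genome.sequence)
    if read_length > n:
        raise ValueError("read_length exceeds genome length")
    n_reads = int(round(coverage * n / read_length))
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, n - read_length + 1, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    labeller = _TruthLabeller(genome)
    reads = []
    for i in range(n_reads):
        s = int(starts[i])
        seq = genome.sequence[s : s + read_length]
        if strands[i] == 1:
            seq = reverse_complement(seq)
        reads.append(
            ReadRecord(
                read_id=f"ref{i:08d}",
                sequence=seq,
                truth_family=labeller.label(s, s + read_length),
            )
        )
    return reads


def _interval_table(genome: SyntheticGenome, read_length: int):
    """Start-position intervals with ChIP sampling weights.

    Covers start positions 0 .. L - read_length; the weight of a start is the
    fold-enrichment of the family covering it (background = 1).
    """
    limit = len(genome.sequence) - read_length + 1
    bounds = [0]
    weights = []
    pos = 0
    for fam, s, e, _ in genome.annotations:
        s, e = min(s, limit), min(e, limit)
        if s > pos:
            bounds.append(s)
            weights.append(1.0)
            pos = s
        if e > pos:
            bounds.append(e)
            weights.append(genome.family_folds.get(fam, 1.0))
            pos = e
    if pos < limit:
        bounds.append(limit)
        weights.append(1.0)
    starts = np.array(bounds[:-1], dtype=np.int64)
    ends = np.array(bounds[1:], dtype=np.int64)
    w = np.array(weights, dtype=float)
    return starts, ends, w


def _sample_positions(
    starts, ends, weights, n: int, rng: np.random.Generator
) -> np.ndarray:
    lengths = ends - starts
    mass = lengths * weights
    total = mass.sum()
    if total <= 0:
        raise ValueError("all sampling weights are zero")
    idx = rng.choice(mass.size, size=n, p=mass / total)
    offset = rng.random(n)
    return (starts[idx] + np.floor(offset * lengths[idx])).astype(np.int64)


def _draw_qualities(
    n_reads: int,
    read_length: int,
    quality_model: Tuple[float, float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    mean, sd, low_rate = quality_model
    q = np.rint(rng.normal(mean, sd, size=(n_reads, read_length)))
    q = np.clip(q, 21, 41).astype(np.int16)
    low = rng.random((n_reads, read_length)) < low_rate
    q[low] = rng.integers(3, 20, size=int(low.sum()), dtype=np.int16)
    return q


def simulate_chip_and_input(
    genome: SyntheticGenome,
    n_chip: int,
    n_input: int,
    read_length: int = 36,
    quality_model: Tuple[float, float, float] = (35.0, 3.0, 0.02),
    seed: int = 0,
) -> Tuple[List[ReadRecord], List[ReadRecord]]:
    """ChIP reads sampled with per-position fold-enrichment weights, input
    reads uniformly; both carry Phred qualities from ``quality_model``
    (mean, sd, low_quality_rate; low-quality bases are Q<20)."""
    if n_chip <= 0 or n_input <= 0:
        raise ValueError("n_chip and n_input must be positive")
    rng = np.random.default_rng(seed)
    starts, ends, weights = _interval_table(genome, read_length)
    labeller = _TruthLabeller(genome)

    def make(prefix: str, n: int, w) -> List[ReadRecord]:
        pos = _sample_positions(starts, ends, w, n, rng)
        strands = rng.integers(0, 2, size=n)
        quals = _draw_qualities(n, read_length, quality_model, rng)
        out = []
        for i in range(n):
            s = int(pos[i])
            seq = genome.sequence[s : s + read_length]
            if strands[i] == 1:
                seq = reverse_complement(seq)
            out.append(
                ReadRecord(
                    read_id=f"{prefix}{i:08d}",
                    sequence=seq,
                    qualities=quals[i],
                    truth_family=labeller.label(s, s + read_length),
                )
            )
        return out

    chip = make("chip", n_chip, weights)
    inp = make("input", n_input, np.ones_like(weights))
    return chip, inp


def expected_enrichment(genome: SyntheticGenome, read_length: int = 36) -> Dict[str, float]:
    """Analytic expectation of realized enrichment per family,
    E_f = f_f / sum_g p_g f_g, with p_g the start-position fraction."""
    starts, ends, weights = _interval_table(genome, read_length)
    lengths = (ends - starts).astype(float)
    denom = float((lengths * weights).sum() / lengths.sum())
    return {fam: fold / denom for fam, fold in genome.family_folds.items()} | {
        "background": 1.0 / denom
    }


# ---------------------------------------------------------------------------
# The pea-like study fixture: 13 enriched satellite families whose monomer
# sizes and AT contents span the observed spectrum (50-2094 bp, AT 0.67-0.77),
# plus one dispersed CRM-like retroelement.  Copy numbers keep every family's
# consensus tiled at >= ~24x by 0.8x reference reads, which (a) keeps each
# family a single connected cluster even after the 10-fold selection thins
# its reads, and (b) makes gaps in the read-start phase spectrum (which
# would cut a contig walk short of two monomer periods) vanishingly rare.
# Total repeat content stays ~4.3% of the genome, so the realized
# enrichment 50 / (0.957 + 0.043*50) ~ 16 sits comfortably above the
# 10-fold cutoff for nearly every individual reference read.
# ---------------------------------------------------------------------------

_PEALIKE_SATELLITES = [
    # (monomer_length, at_content)
    (50, 0.72),
    (120, 0.69),
    (164, 0.73),
    (245, 0.76),
    (510, 0.76),
    (642, 0.73),
    (659, 0.74),
    (867, 0.67),
    (867, 0.76),
    (881, 0.76),
    (1644, 0.74),
    (1813, 0.69),
    (2094, 0.77),
]


def pealike_specs(
    fold_enrichment: float = 50.0,
    divergence: float = 0.03,
    min_family_bp: int = 3500,
    min_copies: int = 30,
) -> List[RepeatSpec]:
    """Specs for the canonical pea-like synthetic fixture (13 satellites + 1 CRM)."""
    specs: List[RepeatSpec] = []
    for k, (m, at) in enumerate(_PEALIKE_SATELLITES, start=1):
        copies = max(min_copies, -(-min_family_bp // m))
        per_locus = copies // 2
        specs.append(
            SatelliteFamilySpec(
                family_id=f"sat{k:02d}",
                monomer_length=m,
                at_content=at,
                n_loci=2,
                copies_per_locus=(per_locus, copies - per_locus),
                divergence=divergence,
                fold_enrichment=fold_enrichment,
            )
        )
    specs.append(
        RetroelementSpec(
            family_id="crm",
            element_length=3000,
            n_insertions=30,
            divergence=divergence,
            fold_enrichment=fold_enrichment,
            at_content=0.70,
        )
    )
    return specs


PEALIKE_REFERENCE_COVERAGE = 0.8


def pealike_genome(
    seed: int,
    fold_enrichment: float = 50.0,
    divergence: float = 0.03,
    background_length: int = 9_100_000,
) -> SyntheticGenome:
    return build_genome(
        pealike_specs(fold_enrichment=fold_enrichment, divergence=divergence),
        background_length=background_length,
        seed=seed,
    )
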