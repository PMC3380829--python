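"""Size arithmetic: genome proportions to Mbp, chromosome and centromere sizes.

All conversions are linear in the haploid genome size G (pea default
4300 Mbp): a family at p percent of the genome occupies p/100 * G Mbp; a
chromosome at relative length r percent spans G * r / 100 Mbp; the
centromeric segment delimited by the outermost CenH3 domains, measured as
a fraction d of the chromosome's integrated DAPI density, spans
d * chromosome Mbp.  Reported Mbp values are rounded half-up to 2 decimals
(raw values are kept in machine output).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import List, Optional

import pandas as pd

PEA_GENOME_MBP = 4300.0


@dataclass(frozen=True)
class GenomeScale:
    genome_size_mbp: float = PEA_GENOME_MBP

    def __post_init__(self) -> None:
        if self.genome_size_mbp <= 0:
            raise ValueError("genome size must be positive")


@dataclass(frozen=True)
class ChromosomeMeasurement:
    chromosome_id: str
    relative_length_pct: float
    centromere_density_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 < self.relative_length_pct <= 100:
            raise ValueError("relative length must be in (0, 100] percent")
        d = self.centromere_density_fraction
        if d is not None and not 0 < d <= 1:
            raise ValueError("centromere density fraction must be in (0, 1]")


def round_half_up(x: float, decimals: int = 2) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(10) ** -decimals, ROUND_HALF_UP))


def genome_proportion_to_mbp(
    proportion_pct: float, genome_size_mbp: float = PEA_GENOME_MBP
) -> float:
    """Mbp occupied by a repeat family at the given genome percentage,
    rounded half-up to 2 decimals."""
    if not 0 <= proportion_pct <= 100:
        raise ValueError("proportion must be a percentage in [0, 100]")
    return round_half_up(proportion_pct / 100.0 * genome_size_mbp)


def chromosome_size_mbp(
    relative_length_pct: float, genome_size_mbp: float = PEA_GENOME_MBP
) -> float:
    """Chromosome size = genome size x relative chromosome length / 100."""
    if not 0 < relative_length_pct <= 100:
        raise ValueError("relative length must be in (0, 100] percent")
    return genome_size_mbp * relative_length_pct / 100.0


def centromere_segment_mbp(density_fraction: float, chromosome_mbp: float) -> float:
    """Size of the segment delimited by the two outermost CenH3 domains."""
    if not 0 < density_fraction <= 1:
        raise ValueError("density fraction must be in (0, 1]")
    if chromosome_mbp <= 0:
        raise ValueError("chromosome size must be positive")
    return density_fraction * chromosome_mbp


def centromere_table(
    measurements: List[ChromosomeMeasurement],
    genome_size_mbp: float = PEA_GENOME_MBP,
) -> pd.DataFrame:
    """Per-chromosome sizes and centromere-segment sizes from a
    measurements table."""
    rows = []
    for m in measurements:
        chrom = chromosome_size_mbp(m.relative_length_pct, genome_size_mbp)
        seg = (
            centromere_segment_mbp(m.centromere_density_fraction, chrom)
            if m.centromere_density_fraction is not None
            else float("nan")
        )
        rows.append(
            {
                "chromosome_id": m.chromosome_id,
                "relative_length_pct": m.relative_length_pct,
                "chromosome_mbp": chrom,
                "centromere_density_fraction": m.centromere_density_fraction,
                "centromere_segment_mbp": seg,
            }
        )
    return pd.DataFrame(rows)


def read_measurements_tsv(path) -> List[ChromosomeMeasurement]:
    """TSV columns: chromosome_id, relative_length_pct,
    [centromere_density_fraction]."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        d = row.get("centromere_density_fraction")
        out.append(
            ChromosomeMeasurement(
                chromosome_id=str(row["chromosome_id"]),
                relative_length_pct=float(row["relative_length_pct"]),
                centromere_density_fraction=None if pd.isna(d) else float(d),
            )
        )
    return out
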