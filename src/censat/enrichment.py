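"""ChIP enrichment: proportion-of-proportions ratios and selection.

The enrichment of a unit (a cluster or a single reference read) is

    E = (c / C) / (i / I)

with c, i the ChIP/input reads mapped to the unit and C, I the total
high-quality (post-QC) ChIP/input read counts.  Units with no input reads
but at least one ChIP read get E = +inf and are selected at any finite
threshold (a pseudocount mode is available but not the default, since
pseudocounts distort the reported enrichment values).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


@dataclass
class EnrichmentRecord:
    unit_id: str
    chip_count: float
    input_count: float
    chip_total: float
    input_total: float
    enrichment: float


def compute_enrichment(
    c: float, C: float, i: float, I: float, zero_policy: str = "infinite"
) -> float:
    """E = (c/C)/(i/I); the zero_policy decides i == 0 (``infinite`` -> +inf
    when c > 0 and 0.0 when c == 0; ``pseudocount`` -> use i = 1)."""
    if C <= 0 or I <= 0:
        raise ValueError("chip and input totals must be positive")
    if c < 0 or i < 0:
        raise ValueError("counts must be non-negative")
    if i == 0:
        if zero_policy == "infinite":
            return math.inf if c > 0 else 0.0
        if zero_policy == "pseudocount":
            i = 1.0
        else:
            raise ValueError(f"unknown zero policy: {zero_policy}")
    return (c / C) / (i / I)


def make_records(
    unit_ids: Sequence[str],
    chip_counts: Sequence[float],
    input_counts: Sequence[float],
    chip_total: float,
    input_total: float,
    zero_policy: str = "infinite",
) -> List[EnrichmentRecord]:
    return [
        EnrichmentRecord(
            unit_id=u,
            chip_count=c,
            input_count=i,
            chip_total=chip_total,
            input_total=input_total,
            enrichment=compute_enrichment(c, chip_total, i, input_total, zero_policy),
        )
        for u, c, i in zip(unit_ids, chip_counts, input_counts)
    ]


def enriched_percentage(n_selected: int, total_references: int) -> float:
    """Selected reads as a percentage of all analyzed reference reads,
    reported at 2 decimals (e.g. 354,717 of 20,527,392 -> 1.73)."""
    if total_references <= 0:
        return 0.0
    return round(100.0 * n_selected / total_references, 2)


def select_enriched_reads(
    records: Iterable[EnrichmentRecord],
    threshold: float = 10.0,
    total_references: Optional[int] = None,
) -> Tuple[List[str], int, float]:
    """Unit ids with E >= threshold (inclusive), their count, and the
    percentage of all reference reads they represent (2 decimals)."""
    selected = [r.unit_id for r in records if r.enrichment >= threshold]
    n = len(selected)
    total = total_references if total_references is not None else n
    return selected, n, enriched_percentage(n, total)


def enrichment_summary(
    records: Sequence[EnrichmentRecord],
    bins_per_decade: int = 4,
) -> Dict[str, object]:
    """Histogram of E over log-spaced bins (edges hit E=1 and E=10 exactly)
    plus a (chip, input) scatter table and depletion summary."""
    if not records:
        raise ValueError("no enrichment records to summarize")
    e = np.array([r.enrichment for r in records], dtype=float)
    finite_pos = e[np.isfinite(e) & (e > 0)]
    n_zero = int(np.count_nonzero(e == 0))
    n_inf = int(np.count_nonzero(np.isinf(e)))
    if finite_pos.size:
        lo = math.floor(np.log10(finite_pos.min()) * bins_per_decade)
        hi = math.ceil(np.log10(finite_pos.max()) * bins_per_decade)
        hi = max(hi, lo + 1)
    else:
        lo, hi = 0, 1
    edges = 10.0 ** (np.arange(lo, hi + 1) / bins_per_decade)
    counts, _ = np.histogram(finite_pos, bins=edges)
    hist = pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}
    )
    scatter = pd.DataFrame(
        {
            "unit_id": [r.unit_id for r in records],
            "chip_count": [r.chip_count for r in records],
            "input_count": [r.input_count for r in records],
            "enrichment": e,
        }
    )
    n = e.size
    return {
        "histogram": hist,
        "scatter": scatter,
        "n_zero": n_zero,
        "n_infinite": n_inf,
        "fraction_depleted": float(np.count_nonzero(e < 1.0)) / n,
        "fraction_enriched_10x": float(np.count_nonzero(e >= 10.0)) / n,
    }
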