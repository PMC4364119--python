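"""Phase accounting, polymorphic yield, and validation-effort estimation.

A marker-development campaign proceeds initial SSRs → Potential Amplifiable
Loci → PCR-positive loci → polymorphic markers.  The *polymorphic yield* is
the fraction of PAL loci that end up polymorphic, and the *validation
effort* for a downstream application is the median number of markers that
application needs divided by that yield — i.e. how many candidate loci one
should expect to push into validation.

Internal values are kept at full precision; reporting rounds half-up to two
decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd


def round2(x: float) -> float:
    """Half-up rounding to 2 decimals (reporting layer only)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PhaseCounts:
    """Locus counts surviving each pipeline phase (monotone non-increasing)."""

    n_initial_ssr: int
    n_pal: int
    n_pcr_positive: int
    n_polymorphic: int

    def __post_init__(self) -> None:
        seq = (self.n_initial_ssr, self.n_pal, self.n_pcr_positive, self.n_polymorphic)
        if any(a < b for a, b in zip(seq, seq[1:])) or seq[-1] < 0:
            raise ValueError(f"phase counts must be monotone non-increasing: {seq}")


@dataclass
class YieldReport:
    counts: PhaseCounts
    pct_pal: float
    pct_pcr: float
    pct_polymorphic_of_initial: float
    polymorphic_yield: float  # percent of PAL
    effort_table: pd.DataFrame | None = None

    def summary(self) -> str:
        c = self.counts
        lines = [
            f"initial SSRs:        {c.n_initial_ssr}",
            f"PAL:                 {c.n_pal} ({self.pct_pal:.2f}%)",
            f"PCR positive:        {c.n_pcr_positive} ({self.pct_pcr:.2f}%)",
            f"polymorphic:         {c.n_polymorphic} ({self.pct_polymorphic_of_initial:.2f}%)",
            f"polymorphic yield:   {self.polymorphic_yield:.2f}% of PAL",
        ]
        if self.effort_table is not None:
            lines.append(self.effort_table.to_string(index=False))
        return "\n".join(lines)


def phase_summary(counts: PhaseCounts) -> YieldReport:
    """Percentages of the initial SSR count surviving each phase."""
    if counts.n_initial_ssr == 0:
        raise ValueError("n_initial_ssr must be positive")
    n0 = counts.n_initial_ssr
    return YieldReport(
        counts=counts,
        pct_pal=round2(100.0 * counts.n_pal / n0),
        pct_pcr=round2(100.0 * counts.n_pcr_positive / n0),
        pct_polymorphic_of_initial=round2(100.0 * counts.n_polymorphic / n0),
        polymorphic_yield=polymorphic_yield(counts.n_polymorphic, counts.n_pal)
        if counts.n_pal
        else 0.0,
    )


def polymorphic_yield(n_polymorphic: int, n_pal: int) -> float:
    """Polymorphic markers as a percentage of PAL loci (2 decimals)."""
    if n_pal <= 0:
        raise ValueError("n_pal must be positive")
    return round2(100.0 * n_polymorphic / n_pal)


def validation_effort(median_markers: float, yield_fraction: float) -> float:
    """Initial SSR count to validate for a target marker tally (2 decimals).

    ``yield_fraction`` is the polymorphic yield as a fraction in (0, 1].
    """
    if not (0.0 < yield_fraction <= 1.0):
        raise ValueError("yield_fraction must lie in (0, 1]")
    return round2(median_markers / yield_fraction)


def effort_table(medians: dict[str, float], yield_fraction: float) -> pd.DataFrame:
    """Per-application validation effort table."""
    rows = [
        {
            "application": label,
            "median_markers": median,
            "required_initial_ssr": validation_effort(median, yield_fraction),
        }
        for label, median in medians.items()
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class Descriptives:
    mean: float
    sd: float | None  # None when fewer than 2 values
    median: float
    min: float
    max: float


def describe(values: Sequence[float]) -> Descriptives:
    """Mean, sample SD (n-1), median, min, max, reported to 2 decimals."""
    if len(values) == 0:
        raise ValueError("empty input")
    arr = np.asarray(values, dtype=float)
    sd = round2(float(arr.std(ddof=1))) if arr.size >= 2 else None
    return Descriptives(
        mean=round2(float(arr.mean())),
        sd=sd,
        median=round2(float(np.median(arr))),
        min=round2(float(arr.min())),
        max=round2(float(arr.max())),
    )
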