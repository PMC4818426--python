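"""Assay arithmetic: in vitro integration ratio and founder summaries.

Small, exactly specified computations on colony and founder count
tables.  Percentages are rounded half-up to the integer percent where a
rounded value is reported, matching how such tables are printed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import EmptyInputError, InvalidArgumentError, UndefinedRatioError


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero (half-up)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ColonyCounts:
    """Colony counts from plating an in vitro integration reaction:
    Kan-resistant colonies report integration products, Amp-resistant
    colonies the total recovered target plasmids.  ``*_plated_fraction``
    is the fraction of the reaction plated on each medium."""

    kan_colonies: int
    amp_colonies: int
    kan_plated_fraction: float = 1.0
    amp_plated_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.kan_colonies < 0 or self.amp_colonies < 0:
            raise InvalidArgumentError("colony counts must be non-negative")
        for f in (self.kan_plated_fraction, self.amp_plated_fraction):
            if not 0.0 < f <= 1.0:
                raise InvalidArgumentError("plated fractions must lie in (0, 1]")


def integration_ratio(counts: ColonyCounts) -> float:
    """Estimated fraction of target plasmids carrying an insertion:
    (Kan colonies / Kan plated fraction) / (Amp colonies / Amp plated
    fraction).  Invariant to scaling both plated fractions together."""
    amp_total = counts.amp_colonies / counts.amp_plated_fraction
    if amp_total == 0:
        raise UndefinedRatioError("no Amp-resistant colonies: total plasmid count undefined")
    return (counts.kan_colonies / counts.kan_plated_fraction) / amp_total


@dataclass(frozen=True)
class FounderRow:
    """One founder category: somatic-pattern class, transposase form and
    the germline counts behind the reported percentages."""

    category: str
    form: str
    positive_founders: int
    total_founders: int
    f1_positive: int = 0
    f1_total: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.positive_founders <= self.total_founders:
            raise InvalidArgumentError("positive founders must be within [0, total]")
        if not 0 <= self.f1_positive <= max(self.f1_total, 0):
            raise InvalidArgumentError("positive F1 must be within [0, total]")


def germline_frequency(row: FounderRow) -> int:
    """Percent of founders transmitting the transgene, to the nearest
    integer percent (half-up)."""
    if row.total_founders < 1:
        raise EmptyInputError("no founders screened")
    return round_half_up(100.0 * row.positive_founders / row.total_founders)


def mosaicism(row: FounderRow) -> float:
    """Percent of a founder's F1 offspring carrying the transgene."""
    if row.f1_total < 1:
        raise EmptyInputError("no F1 offspring screened")
    return 100.0 * row.f1_positive / row.f1_total


def mean_mosaicism(rates: list[float]) -> float:
    """Category-level mosaicism: unweighted mean over founders."""
    if not rates:
        raise EmptyInputError("no founder mosaicism rates")
    return sum(rates) / len(rates)


def founder_summary(rows: list[FounderRow]) -> pd.DataFrame:
    """Tabulated germline frequencies for a set of founder categories."""
    return pd.DataFrame(
        {
            "category": [r.category for r in rows],
            "form": [r.form for r in rows],
            "positive_founders": [r.positive_founders for r in rows],
            "total_founders": [r.total_founders for r in rows],
            "germline_frequency_pct": [germline_frequency(r) for r in rows],
        }
    )
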