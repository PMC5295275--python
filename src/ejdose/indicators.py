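"""Environmental-justice indicator quantification.

Two tract-level indicators are used throughout the package:

* **poverty** -- the fraction of residents whose ratio of income to the
  poverty level over the past 12 months is below 1.5;
* **race/ethnicity** -- the fraction of residents who are non-white.

Each fraction is mapped to an integer score from 1 to 10 by binning [0, 1]
evenly into ten intervals (1 = lowest poverty / most white, 10 = highest).

The module also computes the demographic quantity that drives body-weight
and intake-rate lookup: the *weighted average age* of a tract from grouped
census age-by-sex distributions, and its pooled mean across tracts and
sexes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import DomainError, ValidationError

__all__ = [
    "AgeGroup",
    "assign_score",
    "poverty_fraction",
    "weighted_average_age",
    "pooled_average_age",
    "SCORE_MIN",
    "SCORE_MAX",
]

SCORE_MIN = 1
SCORE_MAX = 10

#: Tolerance on the sum of grouped-age percentages.
PERCENT_SUM_TOL = 1e-6


@dataclass(frozen=True)
class AgeGroup:
    """One grouped-age interval: [lower, upper) in years, and its population share.

    ``upper=None`` marks the open-ended top group (e.g. 60+), whose
    representative age is supplied separately when averaging.
    """

    lower: float
    upper: float | None
    percent: float

    def __post_init__(self) -> None:
        if self.lower < 0:
            raise DomainError(f"age group lower bound must be >= 0, got {self.lower}")
        if self.upper is not None and self.upper <= self.lower:
            raise DomainError(
                f"age group upper bound must exceed lower, got "
                f"[{self.lower}, {self.upper})"
            )
        if not 0.0 <= self.percent <= 1.0:
            raise DomainError(
                f"age group percent must lie in [0, 1], got {self.percent}"
            )

    def midpoint(self, open_ended_value: float) -> float:
        """Representative age: interval midpoint, or the predefined value
        for the open-ended group."""
        if self.upper is None:
            return float(open_ended_value)
        return (self.lower + self.upper) / 2.0


def assign_score(fraction: float) -> int:
    """Map a population fraction in [0, 1] to an integer score 1..10.

    The unit interval is split into ten even bins, half-open on the right
    ([(k-1)/10, k/10) -> score k) with the top bin closed at 1.0, so every
    fraction receives exactly one score and the mapping is monotone.
    """
    if not 0.0 <= fraction <= 1.0 or not math.isfinite(fraction):
        raise DomainError(f"fraction must lie in [0, 1], got {fraction}")
    return min(int(math.floor(fraction * 10.0)) + 1, SCORE_MAX)


def poverty_fraction(income_to_poverty_ratios: Sequence[float]) -> float:
    """Fraction of people with income-to-poverty ratio strictly below 1.5."""
    ratios = list(income_to_poverty_ratios)
    if not ratios:
        raise DomainError("cannot compute a poverty fraction from an empty list")
    for r in ratios:
        if r < 0:
            raise DomainError(f"income-to-poverty ratios must be >= 0, got {r}")
    return sum(1 for r in ratios if r < 1.5) / len(ratios)


def weighted_average_age(
    groups: Iterable[AgeGroup], open_ended_value: float = 90.0
) -> float:
    """Population-weighted average age from a grouped distribution.

    Each group contributes its representative age (interval midpoint, or
    ``open_ended_value`` for the open-ended group) weighted by its
    population share; shares must sum to 1 within ``1e-6``.
    """
    groups = list(groups)
    if not groups:
        raise ValidationError("age distribution has no groups")
    total = sum(g.percent for g in groups)
    if abs(total - 1.0) > PERCENT_SUM_TOL:
        raise ValidationError(
            f"age-group percents must sum to 1 (got {total!r})"
        )
    return sum(g.midpoint(open_ended_value) * g.percent for g in groups)


def pooled_average_age(
    per_tract_sex_ages: "pd.DataFrame | Mapping[str, Sequence[float]]",
) -> float:
    """Mean of the per-sex means of tract weighted ages.

    First average the tract weighted ages within each sex, then average
    the per-sex means.  This equals the simple grand mean only when every
    sex covers the same number of tracts.

    Accepts either a DataFrame with columns ``sex`` and ``age`` (one row
    per tract and sex) or a mapping ``sex -> sequence of tract ages``.
    """
    if isinstance(per_tract_sex_ages, pd.DataFrame):
        df = per_tract_sex_ages
        missing = {"sex", "age"} - set(df.columns)
        if missing:
            raise DomainError(f"missing column(s): {sorted(missing)}")
        by_sex = {sex: list(grp["age"]) for sex, grp in df.groupby("sex")}
    else:
        by_sex = {sex: list(ages) for sex, ages in per_tract_sex_ages.items()}
    if not by_sex:
        raise DomainError("no sexes present")
    for sex, ages in by_sex.items():
        if len(ages) == 0:
            raise DomainError(f"sex {sex!r} has no tract ages")
    sex_means = [sum(ages) / len(ages) for ages in by_sex.values()]
    return sum(sex_means) / len(sex_means)
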