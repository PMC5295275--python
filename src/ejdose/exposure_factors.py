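"""Age-indexed lookup of recommended body weight and daily intake rate.

Risk-assessment practice reads body weight (kg) and medium intake rate
(m^3/day of air, or mg/day of soil/dust) from age-stratified reference
tables such as the EPA Exposure Factors Handbook.  This module represents
such a table as a list of half-open age intervals that tile the age axis
from 0 upward, ending in an open-ended interval, and provides validated
lookup by age.

The packaged default table (``data/exposure_factors_default.csv``) is an
*illustrative* inhalation table, not a reproduction of any handbook: its
values are merely plausible (e.g. 80 kg adult body weight, 16 m^3/day
adult inhalation) so that the pipeline and its tests run without external
documents.  Users analysing real data should supply their own table.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import DomainError, ValidationError

__all__ = [
    "ExposureFactorEntry",
    "validate_table",
    "lookup",
    "load_table",
    "default_inhalation_table",
]


@dataclass(frozen=True)
class ExposureFactorEntry:
    """One age stratum: ``[age_lower, age_upper)`` -> (body weight, intake rate).

    ``age_upper=None`` marks the final open-ended stratum.
    """

    age_lower: float
    age_upper: float | None
    body_weight: float
    intake_rate: float
    intake_units: str = "m3/day"

    def contains(self, age: float) -> bool:
        if age < self.age_lower:
            return False
        return self.age_upper is None or age < self.age_upper


def validate_table(table: Iterable[ExposureFactorEntry]) -> list[str]:
    """Check that entries tile [0, inf) with positive values.

    Returns a list of human-readable violations (empty when the table is
    valid): gaps, overlaps, a missing open-ended tail, a first interval
    not starting at 0, and non-positive body weights or intake rates.
    """
    entries = sorted(table, key=lambda e: e.age_lower)
    violations: list[str] = []
    if not entries:
        return ["table is empty"]
    if entries[0].age_lower != 0:
        violations.append(
            f"first interval starts at {entries[0].age_lower}, expected 0"
        )
    for prev, nxt in zip(entries, entries[1:]):
        if prev.age_upper is None:
            violations.append(
                f"open-ended interval [{prev.age_lower}, inf) is not last"
            )
            break
        if nxt.age_lower > prev.age_upper:
            violations.append(f"gap at [{prev.age_upper}, {nxt.age_lower})")
        elif nxt.age_lower < prev.age_upper:
            violations.append(
                f"overlap between [{prev.age_lower}, {prev.age_upper}) and "
                f"[{nxt.age_lower}, {nxt.age_upper if nxt.age_upper is not None else 'inf'})"
            )
    if entries[-1].age_upper is not None:
        violations.append(
            f"last interval [{entries[-1].age_lower}, {entries[-1].age_upper}) "
            "is not open-ended"
        )
    for e in entries:
        span = f"[{e.age_lower}, {e.age_upper if e.age_upper is not None else 'inf'})"
        if e.body_weight <= 0:
            violations.append(f"non-positive body weight {e.body_weight} in {span}")
        if e.intake_rate <= 0:
            violations.append(f"non-positive intake rate {e.intake_rate} in {span}")
    return violations


def lookup(
    age: float, table: Sequence[ExposureFactorEntry]
) -> tuple[float, float]:
    """Body weight and intake rate for ``age`` from a valid table.

    Intervals are half-open, so an age on an interior boundary belongs to
    the entry whose lower bound equals it.
    """
    if age < 0:
        raise DomainError(f"age must be >= 0, got {age}")
    for entry in table:
        if entry.contains(age):
            return entry.body_weight, entry.intake_rate
    raise DomainError(f"no table entry contains age {age}")


def load_table(path) -> list[ExposureFactorEntry]:
    """Read an exposure-factor table from CSV and validate it.

    Expected columns: ``age_lower``, ``age_upper`` (blank for the
    open-ended tail), ``body_weight_kg``, ``intake_rate`` and optionally
    ``intake_units``.
    """
    df = pd.read_csv(path)
    required = {"age_lower", "age_upper", "body_weight_kg", "intake_rate"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(
            [f"exposure-factor table missing column(s): {sorted(missing)}"]
        )
    entries = []
    for row in df.itertuples(index=False):
        upper = getattr(row, "age_upper")
        entries.append(
            ExposureFactorEntry(
                age_lower=float(row.age_lower),
                age_upper=None if pd.isna(upper) else float(upper),
                body_weight=float(row.body_weight_kg),
                intake_rate=float(row.intake_rate),
                intake_units=str(getattr(row, "intake_units", "m3/day")),
            )
        )
    violations = validate_table(entries)
    if violations:
        raise ValidationError(violations)
    return sorted(entries, key=lambda e: e.age_lower)


def default_inhalation_table() -> list[ExposureFactorEntry]:
    """The packaged illustrative inhalation table (see module docstring)."""
    ref = resources.files("ejdose.data").joinpath("exposure_factors_default.csv")
    with resources.as_file(ref) as path:
        return load_table(path)
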