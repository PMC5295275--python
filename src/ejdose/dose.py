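"""Average daily dose arithmetic and relative-potency mixture scaling.

The average daily dose (ADD) of a contaminant is

    ADD = C * IR * EF * k / BW        [mg per kg body weight per day]

where ``C`` is the contaminant concentration in the exposure medium
(micrograms/m^3 for inhaled air, mg/kg for ingested soil or dust), ``IR``
the daily intake rate of that medium (m^3/day of air, mg/day of soil),
``EF`` the dimensionless exposure factor -- the fraction of time spent in
contact with the contaminated medium -- ``BW`` the average body weight in
kg, and ``k`` an explicit unit-conversion multiplier applied to the
``C * IR`` product.

``k`` is a *required*, visible parameter rather than a hidden constant.
For air inhalation the natural choice is ``1e-3`` (micrograms to mg).  For
soil ingestion the physically standard mass conversion (mg soil to kg
soil) would be ``1e-6``, but the local-scale community scenarios shipped
with this package (:mod:`ejdose.scenarios`) reproduce their reference dose
magnitudes only under ``k = 1e-3``; both conventions are therefore
supported and the fixture records the one it uses.

Mixture doses are expressed as an *index chemical equivalent dose* (ICED):
each component dose is weighted by its relative potency factor (RPF), the
ratio of its inhalation unit risk to that of a designated index chemical,
and the weighted doses are summed.  This assumes dose additivity, i.e.
that mixture components do not interact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from .exceptions import DomainError

__all__ = [
    "DoseParameters",
    "UnitRisk",
    "RPFSet",
    "compute_add",
    "compute_exposure_factor",
    "unit_risk_point_value",
    "compute_rpf",
    "iced_mixture_dose",
    "scenario_dose_ratio",
    "round_sig",
    "display_dose",
    "format_dose",
]


@dataclass(frozen=True)
class DoseParameters:
    """The four ADD variables plus the explicit unit-conversion multiplier.

    Attributes
    ----------
    concentration:
        Contaminant concentration in the exposure medium (ug/m^3 for air,
        mg/kg for soil/dust).  Non-negative.
    intake_rate:
        Daily intake of the medium (m^3/day for air, mg/day for soil).
        Non-negative.
    exposure_factor:
        Fraction of time in contact with the medium, in [0, 1].
    body_weight:
        Average body weight in kg, strictly positive.
    unit_conversion:
        Positive multiplier applied to ``concentration * intake_rate``
        before dividing by body weight (see module docstring).
    """

    concentration: float
    intake_rate: float
    exposure_factor: float
    body_weight: float
    unit_conversion: float

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise DomainError(f"concentration must be >= 0, got {self.concentration}")
        if self.intake_rate < 0:
            raise DomainError(f"intake_rate must be >= 0, got {self.intake_rate}")
        if not 0.0 <= self.exposure_factor <= 1.0:
            raise DomainError(
                f"exposure_factor must lie in [0, 1], got {self.exposure_factor}"
            )
        if self.body_weight <= 0:
            raise DomainError(f"body_weight must be > 0, got {self.body_weight}")
        if self.unit_conversion <= 0:
            raise DomainError(f"unit_conversion must be > 0, got {self.unit_conversion}")


def compute_add(params: DoseParameters) -> float:
    """Average daily dose in mg per kg body weight per day.

    ``ADD = C * IR * EF * k / BW``.  Zero iff any of concentration,
    intake rate or exposure factor is zero.
    """
    return (
        params.concentration
        * params.intake_rate
        * params.exposure_factor
        * params.unit_conversion
        / params.body_weight
    )


def compute_exposure_factor(
    exposed_hours_per_day: float, averaging_hours: float = 24.0
) -> float:
    """Exposure factor: exposure duration divided by averaging time.

    With the default daily averaging time, 3 h of contact per day gives
    ``3 / 24 = 0.125``; round-the-clock contact gives 1.
    """
    if averaging_hours <= 0:
        raise DomainError(f"averaging_hours must be > 0, got {averaging_hours}")
    if not 0.0 <= exposed_hours_per_day <= averaging_hours:
        raise DomainError(
            f"exposed hours ({exposed_hours_per_day}) must lie in "
            f"[0, {averaging_hours}]"
        )
    return exposed_hours_per_day / averaging_hours


@dataclass(frozen=True)
class UnitRisk:
    """Inhalation unit risk of a chemical, per ug/m^3.

    ``value`` is either a single positive float or a ``(low, high)`` pair
    when the source reports a range (e.g. benzene's IRIS range
    2.2e-6 to 7.8e-6 per ug/m^3).
    """

    chemical: str
    value: float | tuple[float, float]

    def __post_init__(self) -> None:
        v = self.value
        if isinstance(v, (tuple, list)):
            if len(v) != 2:
                raise DomainError(
                    f"unit risk range for {self.chemical} must have two bounds"
                )
            low, high = v
            if low <= 0 or high <= 0:
                raise DomainError(f"unit risk bounds for {self.chemical} must be > 0")
            if low > high:
                raise DomainError(
                    f"unit risk range for {self.chemical} has low > high"
                )
            object.__setattr__(self, "value", (float(low), float(high)))
        else:
            if v <= 0:
                raise DomainError(f"unit risk for {self.chemical} must be > 0")
            object.__setattr__(self, "value", float(v))


def unit_risk_point_value(risk: UnitRisk) -> float:
    """Collapse a unit risk to a single number.

    A scalar passes through unchanged; a ``(low, high)`` range returns its
    midpoint, the convention used to obtain a single benzene unit risk
    (5e-6 per ug/m^3) from its published range.
    """
    if isinstance(risk.value, tuple):
        low, high = risk.value
        return (low + high) / 2.0
    return risk.value


def compute_rpf(chemical_risk: float, index_risk: float) -> float:
    """Relative potency factor: chemical unit risk over index unit risk.

    Exactly 1 when both risks are equal (in particular for the index
    chemical itself).
    """
    if chemical_risk <= 0 or index_risk <= 0:
        raise DomainError(
            f"unit risks must be > 0, got {chemical_risk} and {index_risk}"
        )
    if chemical_risk == index_risk:
        return 1.0
    return chemical_risk / index_risk


@dataclass(frozen=True)
class RPFSet:
    """An index chemical and the relative potency factor of each mixture member.

    Invariants: the index chemical maps to exactly 1 and every factor is
    strictly positive.
    """

    index_chemical: str
    rpf: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        rpf = dict(self.rpf)
        if self.index_chemical not in rpf:
            raise DomainError(
                f"index chemical {self.index_chemical!r} missing from RPF map"
            )
        if rpf[self.index_chemical] != 1.0:
            raise DomainError(
                f"RPF of the index chemical must be exactly 1, "
                f"got {rpf[self.index_chemical]}"
            )
        for chem, value in rpf.items():
            if value <= 0:
                raise DomainError(f"RPF of {chem} must be > 0, got {value}")
        object.__setattr__(self, "rpf", rpf)

    @classmethod
    def from_unit_risks(
        cls,
        index_chemical: str,
        unit_risks: Mapping[str, "UnitRisk | float | tuple[float, float]"],
    ) -> "RPFSet":
        """Derive RPFs from inhalation unit risks.

        Each risk may be a scalar, a ``(low, high)`` range (collapsed to
        its midpoint) or a :class:`UnitRisk`.
        """
        risks = {
            chem: unit_risk_point_value(
                v if isinstance(v, UnitRisk) else UnitRisk(chem, v)
            )
            for chem, v in unit_risks.items()
        }
        if index_chemical not in risks:
            raise DomainError(
                f"index chemical {index_chemical!r} has no unit risk entry"
            )
        index_risk = risks[index_chemical]
        rpf = {chem: compute_rpf(r, index_risk) for chem, r in risks.items()}
        return cls(index_chemical=index_chemical, rpf=rpf)


def iced_mixture_dose(doses: Mapping[str, float], rpfs: RPFSet) -> float:
    """Index-chemical-equivalent dose of a mixture: ``sum_i RPF_i * dose_i``.

    Every chemical supplied must have an RPF; missing entries raise rather
    than being silently dropped.
    """
    missing = sorted(set(doses) - set(rpfs.rpf))
    if missing:
        raise DomainError(f"no RPF for chemical(s): {', '.join(missing)}")
    total = 0.0
    for chem, dose in doses.items():
        if dose < 0:
            raise DomainError(f"dose of {chem} must be >= 0, got {dose}")
        total += rpfs.rpf[chem] * dose
    return total


def scenario_dose_ratio(
    dose_a: float,
    dose_b: float,
    round_inputs_to_sig_figs: int | None = None,
) -> float:
    """Ratio of two doses, optionally after rounding each input for display.

    Published comparisons are typically quoted from doses already rounded
    for a table (e.g. 5.06 / 3.91e-4 ~= 12,941), which differs slightly
    from the full-precision ratio; passing ``round_inputs_to_sig_figs=3``
    reproduces the quoted convention.
    """
    if round_inputs_to_sig_figs is not None:
        dose_a = round_sig(dose_a, round_inputs_to_sig_figs)
        dose_b = round_sig(dose_b, round_inputs_to_sig_figs)
    if dose_b == 0:
        raise DomainError("denominator dose is zero (after rounding, if requested)")
    return dose_a / dose_b


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures, ties away from zero."""
    if sig < 1:
        raise DomainError(f"sig must be >= 1, got {sig}")
    if x == 0 or not math.isfinite(x):
        return float(x)
    d = Decimal(repr(float(x)))
    quantum = Decimal(1).scaleb(d.adjusted() - sig + 1)
    return float(d.quantize(quantum, rounding=ROUND_HALF_UP))


def display_dose(x: float) -> float:
    """Round a dose the way the scenario tables print it.

    Values of magnitude >= 0.01 are shown to two decimals (0.23, 5.06);
    smaller values to three significant figures in scientific notation
    (9.10e-3, 3.91e-4).  Ties round away from zero.
    """
    if x == 0 or not math.isfinite(x):
        return float(x)
    if abs(x) >= 0.01:
        return float(Decimal(repr(float(x))).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP))
    return round_sig(x, 3)


def format_dose(x: float) -> str:
    """Human-readable counterpart of :func:`display_dose`."""
    v = display_dose(x)
    if v == 0:
        return "0"
    if abs(v) >= 0.01:
        return f"{v:.2f}"
    return f"{v:.2e}"
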