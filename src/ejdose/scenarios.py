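"""Local-scale community scenario engine.

A *scenario* is a named community with its own dose parameters -- soil
contaminant concentration, ingestion rate, exposure factor and body
weight -- each of which can encode environmental-justice circumstances
(proximity to a contamination site raises C, pica and obesity raise IR,
constant exposure raises EF, and so on).  Running a scenario set yields
each community's average daily dose plus pairwise dose-ratio tables, the
quantity of interest being how many times higher the dose in a
disadvantaged community is than in an affluent one.

The packaged four-community lead-ingestion fixture spans a wealthiest
community (5 mg/kg soil lead, 50 mg/day, EF 0.125, 80 kg) through two
intermediate communities to a severely impacted community (5000 mg/kg,
85 mg/day, EF 1, 84 kg).  Under its recorded unit convention the four
doses display as 3.91e-4, 9.10e-3, 0.23 and 5.06 mg/kg-day, and the
ratio of the displayed extremes is about 12,941.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .dose import (
    DoseParameters,
    compute_add,
    compute_exposure_factor,
    display_dose,
    format_dose,
    scenario_dose_ratio,
)
from .exceptions import ConfigError, DomainError, ValidationError

__all__ = [
    "Scenario",
    "ScenarioReport",
    "run_scenarios",
    "derive_scenario_parameters",
    "table1_scenarios",
    "load_scenarios",
]

#: Significant figures used when quoting ratios of displayed doses.
DISPLAY_SIG_FIGS = 3


@dataclass(frozen=True)
class Scenario:
    """A named community and its dose parameters.

    ``tags`` are free-form environmental-justice indicator labels
    (e.g. ``"food-desert"``, ``"proximity-to-NPL"``) carried through to
    reports; they do not affect the arithmetic.
    """

    name: str
    params: DoseParameters
    tags: tuple[str, ...] = ()


@dataclass
class ScenarioReport:
    """Doses and pairwise ratios for a scenario set.

    ``table`` has one row per scenario (input order preserved) with the
    full-precision dose, the display-rounded dose and its text form.
    ``ratios_full`` and ``ratios_rounded`` are square frames whose
    ``[a, b]`` entry is dose(a)/dose(b); the ``rounded`` variant first
    rounds each dose as displayed, matching how ratios are quoted from a
    printed table.  Both are empty for a single-scenario run.
    """

    table: pd.DataFrame
    ratios_full: pd.DataFrame
    ratios_rounded: pd.DataFrame

    def ratio(self, numerator: str, denominator: str, rounded: bool = True) -> float:
        frame = self.ratios_rounded if rounded else self.ratios_full
        return float(frame.loc[numerator, denominator])

    def to_text(self) -> str:
        lines = ["Scenario doses (mg/kg-day):", self.table.to_string(index=False)]
        if not self.ratios_rounded.empty:
            lines += [
                "",
                "Pairwise dose ratios (rows / columns, display-rounded inputs):",
                self.ratios_rounded.to_string(float_format=lambda v: f"{v:,.6g}"),
            ]
        return "\n".join(lines)


def run_scenarios(scenarios: Sequence[Scenario]) -> ScenarioReport:
    """Compute the dose of every scenario and all pairwise dose ratios."""
    scenarios = list(scenarios)
    if not scenarios:
        raise DomainError("at least one scenario is required")
    names = [s.name for s in scenarios]
    if len(set(names)) != len(names):
        raise ConfigError("scenario names must be unique")
    doses = [compute_add(s.params) for s in scenarios]
    table = pd.DataFrame(
        {
            "name": names,
            "add": doses,
            "add_display": [display_dose(d) for d in doses],
            "add_text": [format_dose(d) for d in doses],
            "tags": [";".join(s.tags) for s in scenarios],
        }
    )
    if len(scenarios) < 2:
        empty = pd.DataFrame(index=pd.Index([], name="name"))
        return ScenarioReport(table=table, ratios_full=empty, ratios_rounded=empty)
    full = pd.DataFrame(
        [[scenario_dose_ratio(a, b) for b in doses] for a in doses],
        index=names,
        columns=names,
    )
    rounded = pd.DataFrame(
        [
            [
                scenario_dose_ratio(display_dose(a), display_dose(b))
                for b in doses
            ]
            for a in doses
        ],
        index=names,
        columns=names,
    )
    return ScenarioReport(table=table, ratios_full=full, ratios_rounded=rounded)


def derive_scenario_parameters(
    base: DoseParameters, adjustments: Mapping[str, float]
) -> DoseParameters:
    """Scale selected fields of a baseline parameter set.

    ``adjustments`` maps field names to multiplicative factors (omitted
    fields keep their baseline value), expressing constructions such as
    "body weight 5% above baseline" (``{"body_weight": 1.05}``) or
    "ingestion rate 70% higher" (``{"intake_rate": 1.7}``).
    """
    valid = {
        "concentration",
        "intake_rate",
        "exposure_factor",
        "body_weight",
        "unit_conversion",
    }
    unknown = set(adjustments) - valid
    if unknown:
        raise ConfigError(f"unknown dose parameter field(s): {sorted(unknown)}")
    changes = {
        name: getattr(base, name) * factor for name, factor in adjustments.items()
    }
    return replace(base, **changes)


def _scenario_from_mapping(
    entry: Mapping, unit_conversion: float, base: Mapping | None
) -> Scenario:
    name = entry.get("name")
    if not name:
        raise ConfigError("every scenario needs a name")
    if "exposure_factor" in entry and "exposed_hours_per_day" in entry:
        raise ConfigError(
            f"scenario {name!r}: give exposure_factor or exposed_hours_per_day, not both"
        )
    if "exposed_hours_per_day" in entry:
        ef = compute_exposure_factor(float(entry["exposed_hours_per_day"]))
    elif "exposure_factor" in entry:
        ef = float(entry["exposure_factor"])
    else:
        raise ConfigError(f"scenario {name!r}: no exposure factor given")
    params = DoseParameters(
        concentration=float(entry["concentration"]),
        intake_rate=float(entry["intake_rate"]),
        exposure_factor=ef,
        body_weight=float(entry["body_weight"]),
        unit_conversion=float(entry.get("unit_conversion", unit_conversion)),
    )
    # Stored values and derivation factors are recorded redundantly;
    # verify they agree so the fixture cannot drift silently.
    if base and "adjustments" in entry:
        adj = entry["adjustments"]
        for fld in ("body_weight", "intake_rate"):
            if fld in adj and fld in base:
                derived = float(base[fld]) * float(adj[fld])
                stored = getattr(params, fld)
                if not math.isclose(derived, stored, rel_tol=1e-9):
                    raise ValidationError(
                        f"scenario {name!r}: stored {fld} {stored} disagrees with "
                        f"base {base[fld]} x {adj[fld]} = {derived}"
                    )
    return Scenario(name=str(name), params=params, tags=tuple(entry.get("tags", ())))


def load_scenarios(path) -> list[Scenario]:
    """Load a scenario set from YAML.

    Top-level keys: ``unit_conversion`` (default for all scenarios),
    optional ``base`` (baseline body weight / intake rate used to check
    each scenario's recorded ``adjustments``), and ``scenarios`` -- a
    list of mappings with ``name``, ``concentration``, ``intake_rate``,
    ``body_weight``, and either ``exposure_factor`` or
    ``exposed_hours_per_day``.
    """
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, Mapping) or "scenarios" not in payload:
        raise ConfigError("scenario file must contain a 'scenarios' list")
    unit_conversion = float(payload.get("unit_conversion", 1e-3))
    base = payload.get("base")
    return [
        _scenario_from_mapping(entry, unit_conversion, base)
        for entry in payload["scenarios"]
    ]


def table1_scenarios() -> list[Scenario]:
    """The packaged four-community lead-ingestion fixture."""
    ref = resources.files("ejdose.data").joinpath("scenarios_table1.yaml")
    with resources.as_file(ref) as path:
        return load_scenarios(path)
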