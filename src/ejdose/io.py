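"""File formats: the tract CSV schema, unit-risk configs, surface JSON.

The tract CSV is flat and spreadsheet-safe -- one row per tract:

    tract_id, nonwhite_fraction, poverty_fraction,
    age_<sex>_<lower>_<upper|open> ... (grouped-age shares per sex),
    conc_<chemical> ...               (ambient concentrations)

Synthetic and real datasets share this schema, so they are
interchangeable downstream.  All floats are written at full precision;
display rounding happens only in human-readable reports.
"""

from __future__ import annotations

import json
import logging
import re
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .dose import RPFSet, UnitRisk
from .exceptions import ConfigError, SchemaError, ValidationError
from .indicators import AgeGroup, PERCENT_SUM_TOL
from .pipeline import ScoreSurface, TractRecord

logger = logging.getLogger(__name__)

__all__ = [
    "read_tracts",
    "write_tracts",
    "load_unit_risk_config",
    "rpf_set_from_config",
    "write_surfaces",
    "read_surfaces",
]

_AGE_COL = re.compile(
    r"^age_(?P<sex>[A-Za-z]+)_(?P<lower>\d+(?:\.\d+)?)_(?P<upper>\d+(?:\.\d+)?|open)$"
)
_CONC_COL = re.compile(r"^conc_(?P<chemical>.+)$")
_REQUIRED = ("tract_id", "nonwhite_fraction", "poverty_fraction")


def _num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)


def write_tracts(records: Sequence[TractRecord], path) -> None:
    """Write tracts to CSV; every record must share one age-group layout."""
    if not records:
        raise ValidationError("no tract records to write")
    first = records[0]
    layout = {
        sex: [(g.lower, g.upper) for g in groups]
        for sex, groups in first.age_distribution.items()
    }
    chemicals = sorted(first.concentrations)
    rows = []
    for rec in records:
        rec_layout = {
            sex: [(g.lower, g.upper) for g in groups]
            for sex, groups in rec.age_distribution.items()
        }
        if rec_layout != layout or sorted(rec.concentrations) != chemicals:
            raise ValidationError(
                f"tract {rec.tract_id} does not share the dataset's column layout"
            )
        # repr() gives the shortest exact representation, so values
        # round-trip bit-for-bit (pandas' default float formatting does not)
        row: dict = {
            "tract_id": rec.tract_id,
            "nonwhite_fraction": repr(rec.nonwhite_fraction),
            "poverty_fraction": repr(rec.poverty_fraction),
        }
        for sex, groups in rec.age_distribution.items():
            for g in groups:
                upper = "open" if g.upper is None else _num(g.upper)
                row[f"age_{sex}_{_num(g.lower)}_{upper}"] = repr(g.percent)
        for chem in chemicals:
            row[f"conc_{chem}"] = repr(rec.concentrations[chem])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _parse_columns(columns) -> tuple[dict, dict]:
    """Split CSV columns into age columns (by sex) and concentration columns."""
    age_cols: dict[str, list[tuple[str, float, float | None]]] = {}
    conc_cols: dict[str, str] = {}
    for col in columns:
        m = _AGE_COL.match(col)
        if m:
            upper = None if m.group("upper") == "open" else float(m.group("upper"))
            age_cols.setdefault(m.group("sex"), []).append(
                (col, float(m.group("lower")), upper)
            )
            continue
        m = _CONC_COL.match(col)
        if m:
            conc_cols[m.group("chemical")] = col
    for sex in age_cols:
        age_cols[sex].sort(key=lambda t: t[1])
    return age_cols, conc_cols


def read_tracts(
    path,
    expected_chemicals: Sequence[str] | None = None,
    strict: bool = True,
) -> list[TractRecord]:
    """Read a tract CSV, validating every row.

    Row-level problems (fractions outside [0, 1], negative concentrations,
    age shares not summing to 1) are reported with their CSV line number.
    With ``strict=True`` (default) any bad row raises a
    :class:`ValidationError` listing all of them; with ``strict=False``
    bad rows are skipped with a logged warning.  Header problems (missing
    required or expected-chemical columns) always raise
    :class:`SchemaError`.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"tract CSV missing required column(s): {missing}")
    age_cols, conc_cols = _parse_columns(df.columns)
    if not conc_cols:
        raise SchemaError("tract CSV has no conc_<chemical> columns")
    if expected_chemicals is not None:
        absent = sorted(set(expected_chemicals) - set(conc_cols))
        if absent:
            raise SchemaError(
                f"tract CSV lacks concentration column(s) for: {absent}"
            )

    records: list[TractRecord] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            ages = {}
            for sex, cols in age_cols.items():
                groups = tuple(
                    AgeGroup(lower=lo, upper=hi, percent=float(row[col]))
                    for col, lo, hi in cols
                )
                total = sum(g.percent for g in groups)
                if abs(total - 1.0) > PERCENT_SUM_TOL:
                    raise ValidationError(
                        f"age shares for sex {sex!r} sum to {total!r}"
                    )
                ages[sex] = groups
            records.append(
                TractRecord(
                    tract_id=str(row["tract_id"]),
                    nonwhite_fraction=float(row["nonwhite_fraction"]),
                    poverty_fraction=float(row["poverty_fraction"]),
                    age_distribution=ages,
                    concentrations={
                        chem: float(row[col]) for chem, col in conc_cols.items()
                    },
                )
            )
        except (ValueError, ValidationError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        if strict:
            raise ValidationError(errors)
        for msg in errors:
            logger.warning("rejected tract row: %s", msg)
    return records


def load_unit_risk_config(path) -> tuple[str, dict[str, UnitRisk]]:
    """Read a unit-risk YAML config: ``index_chemical`` plus a
    ``unit_risk`` map of scalars or ``[low, high]`` ranges."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, Mapping):
        raise ConfigError("unit-risk config must be a mapping")
    try:
        index_chemical = str(payload["index_chemical"])
        risks_raw = payload["unit_risk"]
    except KeyError as exc:
        raise ConfigError(f"unit-risk config missing key: {exc}") from exc
    risks = {
        str(chem): UnitRisk(
            str(chem), tuple(v) if isinstance(v, (list, tuple)) else float(v)
        )
        for chem, v in risks_raw.items()
    }
    return index_chemical, risks


def rpf_set_from_config(path) -> RPFSet:
    """Build an :class:`RPFSet` straight from a unit-risk YAML config."""
    index_chemical, risks = load_unit_risk_config(path)
    return RPFSet.from_unit_risks(index_chemical, risks)


def write_surfaces(surfaces: Sequence[ScoreSurface], path) -> None:
    """Serialise score surfaces to JSON (missing cells become null)."""
    with open(path, "w") as fh:
        json.dump([s.to_dict() for s in surfaces], fh, indent=1)


def read_surfaces(path) -> list[ScoreSurface]:
    with open(path) as fh:
        return [ScoreSurface.from_dict(p) for p in json.load(fh)]
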