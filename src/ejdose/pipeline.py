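"""Tract-level analysis engine.

Joins per-tract ambient concentrations with demographics, computes
single-chemical average daily doses, stratifies tracts by their
environmental-justice scores, and produces trend tables (mean dose per
score, normalised to percent of the per-chemical maximum), 10x10
poverty-by-race dose surfaces, and cumulative mixture layers.

All stratum means are unweighted arithmetic means over tracts; no
population weighting is applied.  Empty strata are reported with a count
of zero and a missing mean -- never a zero dose, since zero is a valid
dose value.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dose import DoseParameters, RPFSet, compute_add
from .exceptions import ConfigError, DomainError, ValidationError
from .exposure_factors import ExposureFactorEntry, lookup
from .indicators import (
    SCORE_MAX,
    SCORE_MIN,
    AgeGroup,
    assign_score,
    pooled_average_age,
    weighted_average_age,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TractRecord",
    "ScoreSurface",
    "per_tract_add",
    "compute_scores",
    "group_mean_by_score",
    "normalize_to_percent",
    "apply_exclusion",
    "build_surface",
    "mixture_layers",
    "plot_surface",
]

SCORES = list(range(SCORE_MIN, SCORE_MAX + 1))


@dataclass(frozen=True)
class TractRecord:
    """One census tract: demographic fractions, grouped ages, concentrations.

    ``age_distribution`` maps sex label -> list of :class:`AgeGroup`;
    ``concentrations`` maps chemical name -> ambient concentration
    (ug/m^3 for air).
    """

    tract_id: str
    nonwhite_fraction: float
    poverty_fraction: float
    age_distribution: Mapping[str, Sequence[AgeGroup]]
    concentrations: Mapping[str, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.nonwhite_fraction <= 1.0:
            raise DomainError(
                f"tract {self.tract_id}: nonwhite_fraction "
                f"{self.nonwhite_fraction} outside [0, 1]"
            )
        if not 0.0 <= self.poverty_fraction <= 1.0:
            raise DomainError(
                f"tract {self.tract_id}: poverty_fraction "
                f"{self.poverty_fraction} outside [0, 1]"
            )
        for chem, c in self.concentrations.items():
            if c < 0:
                raise DomainError(
                    f"tract {self.tract_id}: negative concentration for {chem}"
                )
        object.__setattr__(
            self,
            "age_distribution",
            {sex: tuple(groups) for sex, groups in self.age_distribution.items()},
        )
        object.__setattr__(self, "concentrations", dict(self.concentrations))


def _tract_sex_ages(
    records: Sequence[TractRecord], open_ended_value: float
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Weighted age per (tract, sex); also returns per-tract error records."""
    rows = []
    errors: list[tuple[str, str]] = []
    for rec in records:
        try:
            if not rec.age_distribution:
                raise ValidationError("no age distribution")
            for sex, groups in rec.age_distribution.items():
                rows.append(
                    {
                        "tract_id": rec.tract_id,
                        "sex": sex,
                        "age": weighted_average_age(groups, open_ended_value),
                    }
                )
        except (DomainError, ValidationError) as exc:
            errors.append((rec.tract_id, str(exc)))
            logger.warning("tract %s: invalid age data (%s)", rec.tract_id, exc)
    return pd.DataFrame(rows, columns=["tract_id", "sex", "age"]), errors


def per_tract_add(
    records: Sequence[TractRecord],
    ef_table: Sequence[ExposureFactorEntry],
    *,
    exposure_factor: float = 1.0,
    age_mode: str = "pooled",
    unit_conversion: float = 1e-3,
    open_ended_value: float = 90.0,
) -> pd.DataFrame:
    """Average daily dose for every (tract, chemical) pair.

    In ``pooled`` mode (default) one national average weighted age --
    the mean over sexes of the per-sex tract means -- selects a single
    (body weight, intake rate) pair applied to every tract.  In
    ``per_tract`` mode each tract's own weighted age (averaged over its
    sexes) drives the lookup; tracts with unusable age data are skipped
    with a logged warning in this mode.

    The exposure factor defaults to 1 (continuous contact with ambient
    air); ``unit_conversion`` defaults to 1e-3 (ug -> mg).

    Returns a tidy frame with columns ``tract_id``, ``chemical``, ``dose``.
    """
    if age_mode not in ("pooled", "per_tract"):
        raise ConfigError(f"age_mode must be 'pooled' or 'per_tract', got {age_mode!r}")
    ages, age_errors = _tract_sex_ages(records, open_ended_value)

    bw_ir: dict[str, tuple[float, float]] = {}
    if age_mode == "pooled":
        if ages.empty:
            raise ValidationError("no usable age data to pool")
        pooled = pooled_average_age(ages)
        pair = lookup(pooled, ef_table)
        bw_ir = {rec.tract_id: pair for rec in records}
    else:
        bad = {tract for tract, _ in age_errors}
        per_tract_age = ages.groupby("tract_id")["age"].mean()
        for rec in records:
            if rec.tract_id in bad:
                continue
            bw_ir[rec.tract_id] = lookup(per_tract_age[rec.tract_id], ef_table)

    rows = []
    for rec in records:
        if rec.tract_id not in bw_ir:
            continue
        bw, ir = bw_ir[rec.tract_id]
        for chem, conc in rec.concentrations.items():
            params = DoseParameters(
                concentration=conc,
                intake_rate=ir,
                exposure_factor=exposure_factor,
                body_weight=bw,
                unit_conversion=unit_conversion,
            )
            rows.append(
                {"tract_id": rec.tract_id, "chemical": chem, "dose": compute_add(params)}
            )
    return pd.DataFrame(rows, columns=["tract_id", "chemical", "dose"])


def compute_scores(records: Sequence[TractRecord]) -> pd.DataFrame:
    """Poverty and race scores (1..10) for each tract."""
    return pd.DataFrame(
        {
            "tract_id": [r.tract_id for r in records],
            "poverty_score": [assign_score(r.poverty_fraction) for r in records],
            "race_score": [assign_score(r.nonwhite_fraction) for r in records],
        }
    )


def _full_index(indicator: str, chemicals: Sequence[str]) -> pd.MultiIndex:
    if indicator == "both":
        return pd.MultiIndex.from_product(
            [SCORES, SCORES, chemicals],
            names=["poverty_score", "race_score", "chemical"],
        )
    return pd.MultiIndex.from_product(
        [SCORES, chemicals], names=[f"{indicator}_score", "chemical"]
    )


def group_mean_by_score(
    doses: pd.DataFrame,
    records: Sequence[TractRecord],
    indicator: str = "poverty",
) -> pd.DataFrame:
    """Mean dose per score stratum (or score pair) and chemical.

    ``indicator`` is ``"poverty"``, ``"race"`` or ``"both"`` (the 10x10
    score-pair grid).  Every stratum appears in the output, including
    empty ones, which carry ``n_tracts = 0`` and a missing mean.  Stratum
    tract counts sum to the number of scored tracts for every chemical.
    """
    if indicator not in ("poverty", "race", "both"):
        raise ConfigError(
            f"indicator must be 'poverty', 'race' or 'both', got {indicator!r}"
        )
    scores = compute_scores(records)
    merged = doses.merge(scores, on="tract_id", how="inner")
    chemicals = sorted(doses["chemical"].unique())
    keys = (
        ["poverty_score", "race_score"] if indicator == "both" else [f"{indicator}_score"]
    )
    grouped = merged.groupby(keys + ["chemical"])["dose"].agg(["size", "mean"])
    grouped = grouped.reindex(_full_index(indicator, chemicals))
    out = grouped.reset_index().rename(columns={"size": "n_tracts", "mean": "mean_add"})
    out["n_tracts"] = out["n_tracts"].fillna(0).astype(int)
    return out


def normalize_to_percent(
    summary: pd.DataFrame, value_col: str = "mean_add"
) -> pd.DataFrame:
    """Express stratum means as percent of the per-chemical maximum.

    Within each chemical, every mean is divided by the largest stratum
    mean and multiplied by 100, so the maximum maps to exactly 100.
    Chemicals whose strata are all missing or all zero have no valid
    reference and raise.
    """
    out = summary.copy()
    out["percent"] = np.nan
    for chem, grp in out.groupby("chemical"):
        values = grp[value_col]
        if values.dropna().empty or values.max() <= 0:
            raise DomainError(
                f"cannot normalise chemical {chem!r}: no positive stratum mean"
            )
        # divide first so the maximum maps to exactly 1.0, hence exactly 100
        out.loc[grp.index, "percent"] = (values / values.max()) * 100.0
    return out


def apply_exclusion(
    summaries: pd.DataFrame,
    max_poverty_score: int = 7,
    min_n: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop small or high-poverty strata from reporting output.

    Strata with a poverty score above ``max_poverty_score`` (sample sizes
    there are typically too small to interpret) or with fewer than
    ``min_n`` tracts are removed.  Returns ``(kept, excluded)`` so the
    excluded strata remain available for audit.
    """
    mask = summaries["n_tracts"] >= min_n
    if "poverty_score" in summaries.columns:
        mask &= summaries["poverty_score"] <= max_poverty_score
    kept = summaries[mask].reset_index(drop=True)
    excluded = summaries[~mask].reset_index(drop=True)
    return kept, excluded


@dataclass
class ScoreSurface:
    """A 10x10 grid of mean dose indexed by (poverty score, race score).

    ``grid[i, j]`` is the mean dose of tracts with poverty score ``i+1``
    and race score ``j+1`` (NaN where the stratum is empty); ``counts``
    holds the tract count of every cell and is always fully populated.
    """

    label: str
    grid: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.grid.shape != (10, 10) or self.counts.shape != (10, 10):
            raise ValidationError("surface grids must be 10x10")
        empty = self.counts == 0
        if not np.array_equal(np.isnan(self.grid), empty):
            raise ValidationError(
                "surface cells must be missing exactly where the count is zero"
            )

    def to_dict(self) -> dict:
        grid = [[None if np.isnan(v) else v for v in row] for row in self.grid]
        return {
            "label": self.label,
            "grid": grid,
            "counts": self.counts.tolist(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ScoreSurface":
        grid = np.array(
            [[np.nan if v is None else v for v in row] for row in payload["grid"]],
            dtype=float,
        )
        return cls(
            label=payload["label"],
            grid=grid,
            counts=np.array(payload["counts"], dtype=int),
        )


def build_surface(pair_summaries: pd.DataFrame, chemical_or_layer: str) -> ScoreSurface:
    """Assemble a :class:`ScoreSurface` from ``group_mean_by_score(..., "both")``
    output for one chemical (or mixture-layer label)."""
    sub = pair_summaries[pair_summaries["chemical"] == chemical_or_layer]
    if sub.empty:
        raise DomainError(f"no strata for chemical/layer {chemical_or_layer!r}")
    grid = np.full((10, 10), np.nan)
    counts = np.zeros((10, 10), dtype=int)
    for row in sub.itertuples(index=False):
        i, j = int(row.poverty_score) - 1, int(row.race_score) - 1
        counts[i, j] = row.n_tracts
        if row.n_tracts > 0:
            grid[i, j] = row.mean_add
    return ScoreSurface(label=chemical_or_layer, grid=grid, counts=counts)


def mixture_layers(
    doses: pd.DataFrame,
    rpfs: RPFSet,
    layer_order: Sequence[str],
) -> pd.DataFrame:
    """Cumulative potency-weighted mixture dose per tract, layer by layer.

    Layer ``k`` is ``sum_{j<=k} RPF_j * dose_j`` over the first ``k``
    chemicals of ``layer_order``, which must start with the index
    chemical (whose RPF is 1, so layer 1 is its raw dose).  Layers are
    pointwise non-decreasing in ``k``.

    Returns a tidy frame (``tract_id``, ``chemical``, ``dose``) whose
    ``chemical`` column holds cumulative layer labels such as
    ``"benzene+butadiene"``, so the result feeds directly into
    :func:`group_mean_by_score` and :func:`build_surface`.
    """
    layer_order = list(layer_order)
    if not layer_order:
        raise ConfigError("layer_order is empty")
    if layer_order[0] != rpfs.index_chemical:
        raise ConfigError(
            f"layer_order must start with the index chemical "
            f"{rpfs.index_chemical!r}, got {layer_order[0]!r}"
        )
    missing_rpf = [c for c in layer_order if c not in rpfs.rpf]
    if missing_rpf:
        raise ConfigError(f"no RPF for chemical(s): {', '.join(missing_rpf)}")
    wide = doses.pivot(index="tract_id", columns="chemical", values="dose")
    missing_chem = [c for c in layer_order if c not in wide.columns]
    if missing_chem:
        raise ConfigError(
            f"dose table lacks chemical(s): {', '.join(missing_chem)}"
        )
    if wide[layer_order].isna().any().any():
        raise ValidationError(
            "some tracts lack doses for chemicals in layer_order"
        )
    rows = []
    cumulative = np.zeros(len(wide))
    for k, chem in enumerate(layer_order, start=1):
        cumulative = cumulative + rpfs.rpf[chem] * wide[chem].to_numpy()
        label = "+".join(layer_order[:k])
        rows.append(
            pd.DataFrame(
                {"tract_id": wide.index, "chemical": label, "dose": cumulative}
            )
        )
    return pd.concat(rows, ignore_index=True)


def plot_surface(surface: ScoreSurface, path) -> None:
    """Render a static 3-D surface of mean dose over the score grid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(7, 5))
    ax = fig.add_subplot(projection="3d")
    pov, race = np.meshgrid(SCORES, SCORES, indexing="ij")
    grid = np.ma.masked_invalid(surface.grid)
    ax.plot_surface(pov, race, grid, cmap="viridis", edgecolor="k", linewidth=0.2)
    ax.set_xlabel("poverty score")
    ax.set_ylabel("race score")
    ax.set_zlabel("mean ADD (mg/kg-day)")
    ax.set_title(surface.label)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
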