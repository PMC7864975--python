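"""Regional carbon-budget components: annual net ecosystem exchange (NEE)
from gridded daily rates, riverine DOC+DIC export, net CO2 uptake by the
receiving sea, and the headline comparison ratios.

Sign convention follows the atmospheric-inversion standard: negative NEE
and negative sea-uptake rates denote net CO2 uptake (a sink); inland-water
emission is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import C_MOLAR_MASS, DomainError, G_TO_PG, InputError, KM2_TO_M2
from .uncertainty import UncertainValue, combine_quadrature

__all__ = [
    "NEEGrid",
    "ExportRecord",
    "SeaUptakeSpec",
    "aggregate_nee",
    "sum_export",
    "sea_uptake",
    "budget_ratios",
]


@dataclass
class NEEGrid:
    """Gridded daily NEE in long format.

    ``data`` columns: cell_id, day (1..365), rate_gC_m2_d and optionally
    sd_gC_m2_d (per-cell-day rate standard deviation).  All cells share
    ``cell_area_km2`` (9 x 9 km product cells by default).
    """

    data: pd.DataFrame
    cell_area_km2: float = 81.0

    REQUIRED = ("cell_id", "day", "rate_gC_m2_d")

    def __post_init__(self) -> None:
        if self.cell_area_km2 <= 0:
            raise DomainError("cell area must be positive")
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise InputError(f"NEE grid missing columns: {missing}")
        if self.data.duplicated(["cell_id", "day"]).any():
            raise InputError("NEE grid has duplicate cell-day entries")

    @property
    def n_cells(self) -> int:
        return int(self.data["cell_id"].nunique())

    @property
    def n_days(self) -> int:
        return int(self.data["day"].nunique())


@dataclass(frozen=True)
class ExportRecord:
    """Annual flow-weighted riverine carbon export to the ocean."""

    river: str
    DOC_PgC_yr: float
    DIC_PgC_yr: float

    def __post_init__(self) -> None:
        for v in (self.DOC_PgC_yr, self.DIC_PgC_yr):
            if not np.isnan(v) and v < 0:
                raise InputError("export components must be non-negative")


@dataclass(frozen=True)
class SeaUptakeSpec:
    """Mean areal CO2 flux over a sea surface; negative rate = uptake."""

    mean_rate_mmol_m2_d: float
    surface_area_m2: float
    days: int = 365

    def __post_init__(self) -> None:
        if self.surface_area_m2 <= 0:
            raise DomainError("sea surface area must be positive")
        if not (1 <= self.days <= 366):
            raise DomainError("days must lie in [1, 366]")


def aggregate_nee(grid: NEEGrid, require_complete: bool = True) -> UncertainValue:
    """Annual NEE total, Pg C yr-1 (negative = net land uptake).

    Sum over days of (sum over cells of rate x cell area).  If per-cell
    rate standard deviations are present the uncertainty combines them in
    quadrature within each day and across days; otherwise delta = 0.
    """
    df = grid.data
    if require_complete:
        counts = df.groupby("day", observed=True)["cell_id"].count()
        if counts.nunique() > 1:
            raise InputError(
                "incomplete cell-day coverage; pass require_complete=False "
                "to aggregate anyway"
            )
    area_m2 = grid.cell_area_km2 * KM2_TO_M2
    total = float(df["rate_gC_m2_d"].sum()) * area_m2 * G_TO_PG
    if "sd_gC_m2_d" in df.columns and df["sd_gC_m2_d"].notna().all():
        # quadrature across all cell-days (days combine in quadrature too,
        # so a single pass over cell-day deltas is equivalent)
        deltas = df["sd_gC_m2_d"].to_numpy() * area_m2 * G_TO_PG
        delta = float(np.sqrt(np.sum(deltas**2)))
    else:
        delta = 0.0
    return UncertainValue(total, delta, unit="Pg C yr-1")


def sum_export(records) -> float:
    """Total riverine C export, Pg C yr-1: sum of DOC + DIC over records.

    Missing (NaN) components are treated as zero with a warning.
    """
    records = list(records)
    if not records:
        raise InputError("need at least one export record")
    total = 0.0
    for rec in records:
        doc, dic = rec.DOC_PgC_yr, rec.DIC_PgC_yr
        if np.isnan(doc) or np.isnan(dic):
            warnings.warn(
                f"missing DOC/DIC component for {rec.river}; treated as 0",
                stacklevel=2,
            )
        total += (0.0 if np.isnan(doc) else doc) + (0.0 if np.isnan(dic) else dic)
    return total


def sea_uptake(spec: SeaUptakeSpec) -> float:
    """Net annual sea CO2 flux, Pg C yr-1 (sign preserved from the rate).

    rate (mmol CO2 m-2 d-1) x 1e-3 mol/mmol x 12.011 g C mol-1 x days x
    area (m2) x 1e-15 Pg/g.
    """
    return (
        spec.mean_rate_mmol_m2_d
        * 1e-3
        * C_MOLAR_MASS
        * spec.days
        * spec.surface_area_m2
        * G_TO_PG
    )


def budget_ratios(
    emission_low: float,
    emission_high: float,
    nee: float,
    export: float,
    sea: float,
) -> dict[str, tuple[float, float]]:
    """Headline comparison ratios for an emission bracket [low, high].

    Returns, each as a (low, high) interval:
      - ``emission_vs_nee_percent``: emission as % of |annual NEE|
      - ``emission_vs_export_fold``: emission / riverine export
      - ``emission_vs_sea_fold``: emission / |sea uptake|
    Ratios are scale-invariant to a common unit change.
    """
    if nee == 0 or export == 0 or sea == 0:
        raise DomainError("ratio denominators must be nonzero")
    lo, hi = sorted((emission_low, emission_high))
    return {
        "emission_vs_nee_percent": (100.0 * lo / abs(nee), 100.0 * hi / abs(nee)),
        "emission_vs_export_fold": (lo / export, hi / export),
        "emission_vs_sea_fold": (lo / abs(sea), hi / abs(sea)),
    }
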