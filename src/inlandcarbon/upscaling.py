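"""Zone-stratified upscaling of daily emission rates to annual totals.

Rivers and lakes: every water body draws a daily C emission rate from a
pre-generated pool of 10,000 normal deviates specific to its permafrost
zone and class (re-sampling the pool, rather than drawing fresh normals,
preserves the re-use structure of the original procedure).  The rate is
multiplied by the body's ice-free season length (linear in latitude) and
surface area, then summed by zone.

Main channel: a Monte Carlo over the transect observations (pCO2, pH,
temperature resampled independently per draw) pushed through the flux
equation with chemical enhancement and the seasonal pCO2 adjustment.

Streams and ponds (the extrapolated size classes): fixed published median
rates times extrapolated area times a median season length.

Negative rate draws are retained by default (net uptake is physically
admissible); truncation at zero is switchable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    BodyClass,
    DomainError,
    FittingError,
    G_TO_PG,
    InputError,
    KM2_TO_M2,
    PermafrostZone,
    ZONE_ORDER,
    normalize_zone,
)
from .gas_exchange import (
    ExchangeParams,
    add_ch4,
    bulk_co2_rate,
    enhancement_factor,
    spring_adjust,
)

__all__ = [
    "RateDistribution",
    "SeasonModel",
    "fit_season_model",
    "upscale_inventory",
    "upscale_transect",
    "upscale_fixed_rate",
    "c_yield",
    "floodplain_scenario",
]

DEFAULT_POOL_SIZE = 10_000


@dataclass
class RateDistribution:
    """Zone- and class-specific normal model of the daily C emission rate.

    The pool of ``pool_size`` pre-generated draws is regenerated
    deterministically from ``seed`` and re-sampled during upscaling.
    """

    zone: PermafrostZone
    body_class: BodyClass
    mean: float               # g C m-2 d-1
    sd: float                 # g C m-2 d-1
    pool_size: int = DEFAULT_POOL_SIZE
    seed: int = 0
    truncate_negative: bool = False
    _pool: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise DomainError("rate s.d. must be non-negative")
        if self.pool_size <= 0:
            raise DomainError("pool size must be positive")

    @property
    def pool(self) -> np.ndarray:
        if self._pool is None:
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    [int(self.seed), self.zone.order, hash(self.body_class.value) % (2**31)]
                )
            )
            pool = rng.normal(self.mean, self.sd, self.pool_size)
            if self.truncate_negative:
                pool = np.maximum(pool, 0.0)
            self._pool = pool
        return self._pool

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        idx = rng.integers(0, self.pool_size, n)
        return self.pool[idx]


@dataclass(frozen=True)
class SeasonModel:
    """Ice-free season length (days) as a linear function of latitude."""

    intercept: float          # days
    slope: float              # days per degree N
    body_class: str = "river"
    r_squared: float | None = None

    def predict(self, latitude) -> np.ndarray:
        out = self.intercept + self.slope * np.asarray(latitude, dtype=float)
        return out if np.ndim(out) else float(out)

    def check_positive(self, lat_lo: float, lat_hi: float) -> None:
        if min(self.predict(lat_lo), self.predict(lat_hi)) <= 0:
            raise DomainError(
                "season model predicts non-positive season length inside "
                f"the latitude band [{lat_lo}, {lat_hi}]"
            )


def fit_season_model(latitudes, days, body_class: str = "river") -> SeasonModel:
    """Least-squares fit of season length against latitude."""
    latitudes = np.asarray(latitudes, dtype=float)
    days = np.asarray(days, dtype=float)
    if np.unique(latitudes).size < 3:
        raise FittingError("need >= 3 distinct latitudes for the season fit")
    res = stats.linregress(latitudes, days)
    return SeasonModel(
        intercept=float(res.intercept),
        slope=float(res.slope),
        body_class=body_class,
        r_squared=float(res.rvalue**2),
    )


def _zone_series(df: pd.DataFrame) -> pd.Series:
    return df["zone"].map(lambda z: normalize_zone(z).value)


def upscale_inventory(
    bodies: pd.DataFrame,
    rate_dists: dict[tuple[PermafrostZone, BodyClass], RateDistribution],
    season_models: dict[BodyClass, SeasonModel],
    seed: int,
    ch4_fraction: float = 0.0119,
    apply_ch4: tuple[BodyClass, ...] = (BodyClass.RIVER, BodyClass.MAIN_CHANNEL),
) -> pd.DataFrame:
    """Per-zone, per-class annual C emission from an explicit inventory.

    For each body: draw a daily rate from the matching pool, add the CH4
    share for the configured classes (published lake rates already include
    diffusive CH4), multiply by season length (days, from latitude) and
    surface area (m2); sum per zone and class.

    Returns a tidy frame (zone, body_class, area_km2, emission_PgC_yr).
    Deterministic under ``seed``.
    """
    required = {"body_class", "zone", "surface_area_km2", "latitude"}
    missing = required - set(bodies.columns)
    if missing:
        raise InputError(f"inventory missing columns: {sorted(missing)}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 6]))

    zones = _zone_series(bodies).to_numpy()
    classes = bodies["body_class"].astype(str).to_numpy()
    areas_m2 = bodies["surface_area_km2"].to_numpy(float) * KM2_TO_M2
    lats = bodies["latitude"].to_numpy(float)

    # check coverage first so the error lists every offending stratum
    strata = sorted(set(zip(zones, classes)))
    missing_strata = [
        (z, c)
        for z, c in strata
        if (PermafrostZone(z), BodyClass(c)) not in rate_dists
    ]
    if missing_strata:
        raise InputError(
            "no rate distribution for zone/class strata: " f"{missing_strata}"
        )

    rows = []
    for zone_v, class_v in strata:
        mask = (zones == zone_v) & (classes == class_v)
        n = int(mask.sum())
        zone, body_class = PermafrostZone(zone_v), BodyClass(class_v)
        dist = rate_dists[(zone, body_class)]
        rates = dist.sample(n, rng)
        if body_class in apply_ch4:
            rates = add_ch4(rates, ch4_fraction)
        try:
            season = season_models[body_class].predict(lats[mask])
        except KeyError:
            raise InputError(f"no season model for class {class_v!r}") from None
        emission_g = float(np.sum(rates * season * areas_m2[mask]))
        rows.append(
            {
                "zone": zone_v,
                "body_class": class_v,
                "area_km2": float(areas_m2[mask].sum() / KM2_TO_M2),
                "emission_PgC_yr": emission_g * G_TO_PG,
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(["body_class", "zone"], ignore_index=True)


def _fill_missing_zones(
    groups: dict[PermafrostZone, pd.DataFrame], needed: list[PermafrostZone]
) -> dict[PermafrostZone, pd.DataFrame]:
    """Fill zones with no samples from the nearest sampled zone to the
    south (the continuous zone borrows from discontinuous)."""
    filled = dict(groups)
    for zone in needed:
        if zone in filled:
            continue
        donor = None
        for candidate in reversed(ZONE_ORDER[: zone.order]):
            if candidate in groups:
                donor = candidate
                break
        if donor is None:
            raise InputError(
                f"zone {zone.value} has no samples and no southern neighbour to fill from"
            )
        filled[zone] = groups[donor]
    return filled


def upscale_transect(
    samples: pd.DataFrame,
    zone_areas_km2: dict[PermafrostZone, float],
    zone_seasons_days: dict[PermafrostZone, float],
    params: ExchangeParams | None = None,
    n_draws: int = 100_000,
    seed: int = 0,
    apply_spring_adjustment: bool = True,
) -> pd.DataFrame:
    """Main-channel annual C emission per zone from an underway transect.

    Per zone and per draw: resample pCO2, pH and temperature independently
    from the zone's observations, apply the seasonal pCO2 adjustment,
    evaluate the flux equation with chemical enhancement and the median k,
    add the CH4 share; the zone's mean daily rate then scales by area and
    season length.  Zones without samples (the ship never reached the
    continuous zone) are filled from the adjacent sampled zone to the
    south.

    Returns a frame (zone, body_class, area_km2, emission_PgC_yr,
    rate_mean_gC_m2_d, rate_median_gC_m2_d, rate_sd_gC_m2_d).
    """
    params = params or ExchangeParams()
    required = {"zone", "pCO2_uatm", "temp_C", "pH"}
    missing = required - set(samples.columns)
    if missing:
        raise InputError(f"transect missing columns: {sorted(missing)}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))

    zone_labels = _zone_series(samples)
    groups = {
        PermafrostZone(z): g for z, g in samples.groupby(zone_labels, observed=True)
    }
    needed = sorted(zone_areas_km2, key=lambda z: z.order)
    groups = _fill_missing_zones(groups, needed)

    rows = []
    for zone in needed:
        g = groups[zone]
        pco2 = g["pCO2_uatm"].to_numpy(float)
        ph = np.minimum(g["pH"].to_numpy(float), 7.999)
        temp = g["temp_C"].to_numpy(float)
        dr_pco2 = rng.choice(pco2, n_draws, replace=True)
        dr_ph = rng.choice(ph, n_draws, replace=True)
        dr_temp = rng.choice(temp, n_draws, replace=True)
        if apply_spring_adjustment:
            dr_pco2 = spring_adjust(dr_pco2)
        if params.enhancement_enabled:
            alpha = enhancement_factor(dr_ph, dr_temp, params.k)
        else:
            alpha = 1.0
        rates = bulk_co2_rate(dr_pco2, params.pCO2_atm, dr_temp, params.k, alpha)
        rates = add_ch4(rates, params.ch4_fraction)
        mean_rate = float(rates.mean())
        area_m2 = zone_areas_km2[zone] * KM2_TO_M2
        season = zone_seasons_days[zone]
        rows.append(
            {
                "zone": zone.value,
                "body_class": BodyClass.MAIN_CHANNEL.value,
                "area_km2": zone_areas_km2[zone],
                "emission_PgC_yr": mean_rate * area_m2 * season * G_TO_PG,
                "rate_mean_gC_m2_d": mean_rate,
                "rate_median_gC_m2_d": float(np.median(rates)),
                "rate_sd_gC_m2_d": float(rates.std(ddof=1)),
            }
        )
    return pd.DataFrame(rows)


def upscale_fixed_rate(area_km2: float, rate_gC_m2_d: float, season_days: float) -> float:
    """Annual emission, Pg C yr-1, from a fixed daily rate over an area.

    area (m2) x rate x season / 1e15.  All inputs must be positive; a
    zero area gives exactly 0.
    """
    if area_km2 < 0 or rate_gC_m2_d < 0 or season_days < 0:
        raise DomainError("area, rate and season must be non-negative")
    return area_km2 * KM2_TO_M2 * rate_gC_m2_d * season_days * G_TO_PG


def c_yield(emission_PgC_yr: float, land_area_km2: float) -> float:
    """Carbon yield: emission normalised to contributing land area.

    Returns g C per m2 of land per year: emission x 1e15 / (land x 1e6).
    """
    if land_area_km2 <= 0:
        raise DomainError("land area must be > 0")
    return emission_PgC_yr / G_TO_PG / (land_area_km2 * KM2_TO_M2)


def floodplain_scenario(
    zone_emissions: pd.DataFrame,
    zone_seasons_days: dict[PermafrostZone, float] | float,
    area_increase: float = 0.85,
    flood_days: float = 30.0,
    include_classes: tuple[BodyClass, ...] = (
        BodyClass.MAIN_CHANNEL,
        BodyClass.RIVER,
        BodyClass.STREAM,
        BodyClass.LAKE,
    ),
) -> float:
    """Percent increase in annual emission from a spring-flood area pulse.

    The flooded increment applies each zone's mean daily rate (emission /
    season / area, implicit) to ``area_increase`` x area for
    ``flood_days``: extra_z = E_z * area_increase * flood_days / season_z,
    restricted to lotic + lake classes by default.  With a uniform season
    s the closed form is 100 * area_increase * flood_days / s.
    """
    if area_increase < 0:
        raise DomainError("area_increase must be >= 0")
    include = {c.value for c in include_classes}
    sel = zone_emissions[zone_emissions["body_class"].isin(include)]
    base_total = float(zone_emissions["emission_PgC_yr"].sum())
    if base_total == 0:
        raise DomainError("base emission is zero")
    extra = 0.0
    for _, row in sel.iterrows():
        zone = normalize_zone(row["zone"])
        season = (
            zone_seasons_days
            if np.isscalar(zone_seasons_days)
            else zone_seasons_days[zone]
        )
        if flood_days > season:
            raise DomainError(
                f"flood_days {flood_days} exceeds season length {season} in {zone.value}"
            )
        extra += row["emission_PgC_yr"] * area_increase * flood_days / season
    return 100.0 * extra / base_total
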