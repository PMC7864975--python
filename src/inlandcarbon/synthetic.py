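"""Synthetic landscape generator.

Generates every input the real analysis obtained from hydrography
databases, field campaigns and satellite products, with the statistical
structure the upscaling assumes, so the whole pipeline is testable
without any external downloads:

* a water-body inventory (main-channel segments, rivers, lakes) with
  truncated-Pareto river widths (shape 0.93) and lake areas (shape 1.19),
  permafrost-zone assignment and per-zone uniform latitudes;
* an underway pCO2 transect (lognormal, moment-matched to mean 1546 and
  s.d. 882 uatm) whose continuous-zone samples are deliberately missing;
* per-zone field observations of daily C emission rates;
* a gridded daily NEE product with a summer uptake pulse.

Every generator is a pure function of (config, seed): fixed seed means
bit-identical output.  Per-product seeds are derived from the master seed
with distinct stream keys, so generating products in any order or in
isolation yields the same draws.
"""

from __future__ import annotations

import copy
import hashlib
import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .budget import ExportRecord, NEEGrid, SeaUptakeSpec
from .core import (
    BodyClass,
    ConfigurationError,
    LAKE_MIN_AREA_KM2,
    PermafrostZone,
    RIVER_MIN_WIDTH_M,
    ZONE_ORDER,
    ZoneInfo,
)

__all__ = [
    "LandscapeConfig",
    "default_config",
    "generate_inventory",
    "generate_transect",
    "generate_rate_observations",
    "generate_nee_grid",
]

# stream keys mixed into the master seed, one per generated product
_STREAM_KEYS = {
    "inventory": 1,
    "transect": 2,
    "rates": 3,
    "nee": 4,
    "rate_pools": 5,
    "upscale": 6,
}


def _substream(seed: int, product: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM_KEYS[product]]))


@dataclass
class LandscapeConfig:
    """Validated landscape-generator configuration.

    Thin wrapper over the nested mapping loaded from YAML; see
    ``data/default_config.yaml`` for the documented schema and the
    calibration notes.  ``raw`` keeps the original mapping for hashing and
    manifest output.
    """

    raw: dict

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ---------------------------------------------------------

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def scale(self) -> float:
        return float(self.raw.get("scale", 1.0))

    def zone_infos(self) -> dict[PermafrostZone, ZoneInfo]:
        out = {}
        for zone in ZONE_ORDER:
            spec = self.raw["zones"][zone.value]
            out[zone] = ZoneInfo(
                zone=zone,
                land_area_km2=float(spec["land_area_km2"]),
                latitude_band=tuple(float(v) for v in spec["latitude_band"]),
            )
        return out

    def rate_params(self, body_class: str) -> dict[PermafrostZone, tuple[float, float]]:
        """(mean, sd) of the daily C emission rate per zone for a class."""
        try:
            table = self.raw["rates"][body_class]
        except KeyError:
            raise ConfigurationError(f"no rate table for class {body_class!r}") from None
        out = {}
        for zone in ZONE_ORDER:
            if zone.value not in table:
                raise ConfigurationError(
                    f"missing rate parameters for zone {zone.value} ({body_class})"
                )
            entry = table[zone.value]
            out[zone] = (float(entry["mean"]), float(entry["sd"]))
        return out

    def season_coefficients(self, body_class: str) -> tuple[float, float]:
        m = self.raw["season_models"][body_class]
        return float(m["intercept"]), float(m["slope"])

    @property
    def stream_season_days(self) -> float:
        return float(self.raw["stream_season_days"])

    @property
    def fixed_rates(self) -> dict[str, float]:
        return {k: float(v) for k, v in self.raw["fixed_rates"].items()}

    def export_records(self) -> list[ExportRecord]:
        return [
            ExportRecord(
                river=str(e["river"]),
                DOC_PgC_yr=float(e["DOC_PgC_yr"]),
                DIC_PgC_yr=float(e["DIC_PgC_yr"]),
            )
            for e in self.raw["exports"]
        ]

    def sea_uptake_spec(self) -> SeaUptakeSpec:
        k = self.raw["kara_sea"]
        return SeaUptakeSpec(
            mean_rate_mmol_m2_d=float(k["mean_rate_mmol_m2_d"]),
            surface_area_m2=float(k["surface_area_km2"]) * 1e6,
            days=int(k["days"]),
        )

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.raw, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()

    def replace(self, **updates) -> "LandscapeConfig":
        """Copy with top-level keys replaced (e.g. seed=..., scale=...)."""
        raw = copy.deepcopy(self.raw)
        raw.update(updates)
        return LandscapeConfig(raw)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        raw = self.raw
        for key in ("seed", "zones", "rivers", "lakes", "rates", "season_models",
                    "transect", "nee", "fixed_rates"):
            if key not in raw:
                raise ConfigurationError(f"config missing required key {key!r}")
        if self.scale <= 0:
            raise ConfigurationError("scale must be > 0")
        for zone in ZONE_ORDER:
            if zone.value not in raw["zones"]:
                raise ConfigurationError(f"config missing zone {zone.value}")
        self.zone_infos()  # validates land areas / bands
        for name in ("rivers", "streams", "main_channel"):
            if name in raw and int(raw[name].get("count", 0)) < 0:
                raise ConfigurationError(f"{name} count must be >= 0")
        for name in ("rivers", "streams"):
            if name in raw:
                wp = raw[name]["width_pareto"]
                if float(wp["shape"]) <= 0:
                    raise ConfigurationError("Pareto shape must be > 0")
                if not 0 < float(wp["min_m"]) < float(wp["max_m"]):
                    raise ConfigurationError("require 0 < min width < max width")
        ap = raw["lakes"]["area_pareto"]
        if float(ap["shape"]) <= 0:
            raise ConfigurationError("Pareto shape must be > 0")
        if not 0 < float(ap["min_km2"]) < float(ap["max_km2"]):
            raise ConfigurationError("require 0 < min area < max area")
        for n in raw["lakes"]["zone_counts"].values():
            if int(n) < 0:
                raise ConfigurationError("lake counts must be >= 0")
        tr = raw["transect"]
        pco2 = tr["pCO2"]
        if float(pco2["mean_uatm"]) <= 0 or float(pco2["sd_uatm"]) < 0:
            raise ConfigurationError("transect pCO2 mean must be > 0 and sd >= 0")
        family = pco2.get("family", "lognormal")
        if family not in ("lognormal", "normal"):
            raise ConfigurationError(f"unknown pCO2 family {family!r}")
        if family == "normal" and float(pco2["sd_uatm"]) >= float(pco2["mean_uatm"]):
            raise ConfigurationError(
                "normal pCO2 family with sd >= mean violates positivity; "
                "use the lognormal family"
            )
        if int(raw["nee"]["n_cells"]) <= 0 or float(raw["nee"]["cell_area_km2"]) <= 0:
            raise ConfigurationError("NEE grid size and cell area must be positive")

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "LandscapeConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))


def default_config() -> LandscapeConfig:
    """The calibrated configuration shipped with the package."""
    text = (
        importlib.resources.files("inlandcarbon")
        .joinpath("data/default_config.yaml")
        .read_text()
    )
    return LandscapeConfig(yaml.safe_load(text))


# --- samplers -------------------------------------------------------------


def _truncated_pareto(rng, shape: float, lo: float, hi: float, n: int) -> np.ndarray:
    """Inverse-CDF draws from a Pareto(shape) truncated to [lo, hi]."""
    u = rng.random(n)
    a, b = lo ** (-shape), hi ** (-shape)
    return (a - u * (a - b)) ** (-1.0 / shape)


def _lognormal_mean(rng, mean: float, log_sd: float, n: int) -> np.ndarray:
    """Lognormal draws with arithmetic mean `mean` and log-scale sd."""
    mu = np.log(mean) - 0.5 * log_sd**2
    return rng.lognormal(mu, log_sd, n)


def _allocate_counts(total: int, fractions: dict[str, float]) -> dict[PermafrostZone, int]:
    zones = [z for z in ZONE_ORDER if z.value in fractions]
    counts = {z: int(round(total * float(fractions[z.value]))) for z in zones}
    # fix rounding drift on the largest class
    drift = total - sum(counts.values())
    if drift:
        biggest = max(zones, key=lambda z: counts[z])
        counts[biggest] += drift
    return counts


# --- generators -----------------------------------------------------------


def generate_inventory(config: LandscapeConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate the water-body inventory as a tidy table.

    Columns: body_id, body_class, zone, surface_area_km2, width_m (NaN for
    lentic bodies), latitude.  Lotic areas are width x length with
    lognormal segment lengths; class boundaries (90 m, 0.01 km2, ...) hold
    by construction of the truncated samplers.
    """
    rng = _substream(seed if seed is not None else config.seed, "inventory")
    zone_infos = config.zone_infos()
    frames = []

    def lat_for(zone: PermafrostZone, n: int) -> np.ndarray:
        lo, hi = zone_infos[zone].latitude_band
        return rng.uniform(lo, hi, n)

    # lotic classes -------------------------------------------------------
    for name, body_class in (
        ("main_channel", BodyClass.MAIN_CHANNEL),
        ("rivers", BodyClass.RIVER),
        ("streams", BodyClass.STREAM),
    ):
        spec = config.raw.get(name)
        if spec is None:
            continue
        total = int(round(int(spec["count"]) * config.scale))
        if total <= 0:
            continue
        fractions = spec.get(
            "zone_fractions", {z.value: 0.2 for z in ZONE_ORDER}
        )
        counts = _allocate_counts(total, fractions)
        for zone, n in counts.items():
            if n <= 0:
                continue
            if "width_pareto" in spec:
                wp = spec["width_pareto"]
                widths = _truncated_pareto(
                    rng, float(wp["shape"]), float(wp["min_m"]), float(wp["max_m"]), n
                )
            else:
                wl = spec["width_lognormal"]
                widths = np.maximum(
                    _lognormal_mean(rng, float(wl["mean_m"]), float(wl["log_sd"]), n),
                    RIVER_MIN_WIDTH_M,
                )
            ll = spec["length_lognormal"]
            lengths = _lognormal_mean(rng, float(ll["mean_m"]), float(ll["log_sd"]), n)
            frames.append(
                pd.DataFrame(
                    {
                        "body_class": body_class.value,
                        "zone": zone.value,
                        "surface_area_km2": widths * lengths / 1e6,
                        "width_m": widths,
                        "latitude": lat_for(zone, n),
                    }
                )
            )

    # lentic classes ------------------------------------------------------
    for name, body_class in (("lakes", BodyClass.LAKE), ("ponds", BodyClass.POND)):
        spec = config.raw.get(name)
        if spec is None:
            continue
        ap = spec["area_pareto"]
        for zone in ZONE_ORDER:
            n = int(round(int(spec["zone_counts"].get(zone.value, 0)) * config.scale))
            if n <= 0:
                continue
            areas = _truncated_pareto(
                rng, float(ap["shape"]), float(ap["min_km2"]), float(ap["max_km2"]), n
            )
            frames.append(
                pd.DataFrame(
                    {
                        "body_class": body_class.value,
                        "zone": zone.value,
                        "surface_area_km2": areas,
                        "width_m": np.nan,
                        "latitude": lat_for(zone, n),
                    }
                )
            )

    if not frames:
        inv = pd.DataFrame(
            columns=["body_class", "zone", "surface_area_km2", "width_m", "latitude"]
        )
    else:
        inv = pd.concat(frames, ignore_index=True)
    inv.insert(0, "body_id", np.arange(len(inv), dtype=np.int64))
    inv["body_class"] = inv["body_class"].astype("category")
    inv["zone"] = inv["zone"].astype("category")
    return inv


def generate_transect(config: LandscapeConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate the main-channel underway gas transect.

    Columns: sample_id, zone, pCO2_uatm, temp_C, pressure_kPa, pH.  pCO2
    is lognormal with moments matched to the configured mean/s.d.
    (positivity); pH is normal truncated below the configured maximum
    (default 8); the continuous zone is intentionally absent so downstream
    code must exercise the fill-from-discontinuous rule.
    """
    from scipy import stats

    rng = _substream(seed if seed is not None else config.seed, "transect")
    tr = config.raw["transect"]
    frames = []
    mean = float(tr["pCO2"]["mean_uatm"])
    sd = float(tr["pCO2"]["sd_uatm"])
    family = tr["pCO2"].get("family", "lognormal")
    ph_mean, ph_sd = float(tr["pH"]["mean"]), float(tr["pH"]["sd"])
    ph_max = float(tr["pH"].get("max", 8.0))
    t_mean, t_sd = float(tr["temp"]["mean_C"]), float(tr["temp"]["sd_C"])
    p_mean, p_sd = float(tr["pressure"]["mean_kPa"]), float(tr["pressure"]["sd_kPa"])

    for zone_label, n in tr["n_per_zone"].items():
        n = int(round(int(n) * config.scale))
        if n <= 0:
            continue
        if sd == 0:
            pco2 = np.full(n, mean)
        elif family == "lognormal":
            sigma2 = np.log1p((sd / mean) ** 2)
            mu = np.log(mean) - sigma2 / 2.0
            pco2 = rng.lognormal(mu, np.sqrt(sigma2), n)
        else:  # validated normal family (sd < mean)
            pco2 = np.abs(rng.normal(mean, sd, n))
        if ph_sd > 0:
            upper = (ph_max - ph_mean) / ph_sd
            ph = stats.truncnorm.rvs(
                -np.inf, upper, loc=ph_mean, scale=ph_sd, size=n, random_state=rng
            )
        else:
            ph = np.full(n, min(ph_mean, ph_max - 1e-6))
        frames.append(
            pd.DataFrame(
                {
                    "zone": zone_label,
                    "pCO2_uatm": pco2,
                    "temp_C": rng.normal(t_mean, t_sd, n),
                    "pressure_kPa": rng.normal(p_mean, p_sd, n),
                    "pH": ph,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "sample_id", np.arange(len(out), dtype=np.int64))
    return out


def generate_rate_observations(
    config: LandscapeConfig, seed: int | None = None
) -> pd.DataFrame:
    """Per-zone field observations of daily C emission rates.

    Columns: body_class, zone, latitude, rate_gC_m2_d.  Site counts per
    zone follow the configured field-campaign layout; rates are normal
    draws from the zone- and class-specific distributions.
    """
    rng = _substream(seed if seed is not None else config.seed, "rates")
    sites = config.raw["field_sites"]
    zone_infos = config.zone_infos()
    frames = []
    for body_class, key in (("river", "river_obs_per_zone"), ("lake", "lake_obs_per_zone")):
        params = config.rate_params(body_class)
        for zone in ZONE_ORDER:
            n = int(sites[key].get(zone.value, 0))
            if n <= 0:
                continue
            mean, sd = params[zone]
            lo, hi = zone_infos[zone].latitude_band
            frames.append(
                pd.DataFrame(
                    {
                        "body_class": body_class,
                        "zone": zone.value,
                        "latitude": rng.uniform(lo, hi, n),
                        "rate_gC_m2_d": rng.normal(mean, sd, n),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def generate_nee_grid(config: LandscapeConfig, seed: int | None = None) -> NEEGrid:
    """Gridded daily NEE with a seasonal cycle (net uptake in summer).

    Daily cell rate = winter respiration baseline minus a Gaussian summer
    uptake pulse, plus a persistent per-cell offset; the per-cell-day
    standard deviation is a fraction of |rate| with a floor.
    """
    rng = _substream(seed if seed is not None else config.seed, "nee")
    nee = config.raw["nee"]
    n_cells = int(nee["n_cells"])
    days = np.arange(1, 366)
    pulse = float(nee["summer_pulse_amplitude"]) * np.exp(
        -0.5 * ((days - float(nee["summer_pulse_day"])) / float(nee["summer_pulse_width_days"])) ** 2
    )
    base = float(nee["winter_rate"]) - pulse  # g C m-2 d-1, one value per day
    offsets = rng.normal(0.0, float(nee["cell_noise_sd"]), n_cells)
    rate = base[None, :] + offsets[:, None]  # (cells, days)
    sd = float(nee["rate_sd_fraction"]) * np.abs(rate) + float(nee["rate_sd_floor"])
    cell_ids = np.repeat(np.arange(n_cells, dtype=np.int64), days.size)
    data = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "day": np.tile(days, n_cells),
            "rate_gC_m2_d": rate.ravel(),
            "sd_gC_m2_d": sd.ravel(),
        }
    )
    return NEEGrid(data=data, cell_area_km2=float(nee["cell_area_km2"]))
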