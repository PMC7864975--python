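"""Upscaling: season regression, inventory and transect Monte Carlo,
fixed-rate products, yields and the flood scenario."""

import numpy as np
import pandas as pd
import pytest

from inlandcarbon.core import BodyClass, DomainError, FittingError, InputError, PermafrostZone
from inlandcarbon.gas_exchange import ExchangeParams
from inlandcarbon.upscaling import (
    RateDistribution,
    SeasonModel,
    c_yield,
    fit_season_model,
    floodplain_scenario,
    upscale_fixed_rate,
    upscale_inventory,
    upscale_transect,
)

Z = PermafrostZone


def make_inventory(n=20, zone="absent", body_class="river", area=1.0, lat=60.0):
    return pd.DataFrame(
        {
            "body_class": body_class,
            "zone": zone,
            "surface_area_km2": np.full(n, area),
            "latitude": np.full(n, lat),
        }
    )


def make_dists(mean, sd=0.0, seed=0, classes=(BodyClass.RIVER, BodyClass.LAKE)):
    return {
        (z, c): RateDistribution(zone=z, body_class=c, mean=mean, sd=sd, seed=seed)
        for z in Z
        for c in classes
    }


UNIT_SEASON = {c: SeasonModel(intercept=1.0, slope=0.0, body_class=c.value)
               for c in (BodyClass.RIVER, BodyClass.LAKE, BodyClass.MAIN_CHANNEL)}


class TestSeasonModel:
    def test_noiseless_line_recovered_exactly(self):
        lats = np.linspace(55, 73, 30)
        model = fit_season_model(lats, 600.0 - 7.0 * lats)
        assert model.intercept == pytest.approx(600.0, abs=1e-8)
        assert model.slope == pytest.approx(-7.0, abs=1e-9)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_fit_quality_mirrors_field_regressions(self):
        rng = np.random.default_rng(5)
        lats = rng.uniform(55, 73, 116)
        days = 600.0 - 7.0 * lats + rng.normal(0, 4.0, lats.size)
        model = fit_season_model(lats, days)
        assert model.r_squared > 0.95

    def test_constant_latitude_rejected(self):
        with pytest.raises(FittingError):
            fit_season_model(np.full(10, 60.0), np.full(10, 180.0))

    def test_positivity_check(self):
        model = SeasonModel(intercept=100.0, slope=-7.0)
        with pytest.raises(DomainError):
            model.check_positive(55.0, 73.0)


class TestInventoryUpscaling:
    def test_zero_rates_give_zero_emission(self):
        inv = make_inventory(50)
        out = upscale_inventory(inv, make_dists(0.0), UNIT_SEASON, seed=1)
        assert (out.emission_PgC_yr == 0).all()

    def test_doubling_areas_doubles_emissions(self):
        inv = make_inventory(200, area=0.5)
        dists = make_dists(2.0, sd=1.0)
        out1 = upscale_inventory(inv, dists, UNIT_SEASON, seed=3)
        inv2 = inv.assign(surface_area_km2=inv.surface_area_km2 * 2)
        out2 = upscale_inventory(inv2, make_dists(2.0, sd=1.0), UNIT_SEASON, seed=3)
        assert out2.emission_PgC_yr.to_numpy() == pytest.approx(
            2 * out1.emission_PgC_yr.to_numpy(), rel=1e-12
        )

    def test_units_audit_one_gram_one_km2_one_day(self):
        # 1 g C m-2 d-1 over 1 km2 for a 1-day season is exactly 1e-9 Pg
        inv = make_inventory(1, area=1.0)
        out = upscale_inventory(
            inv, make_dists(1.0), UNIT_SEASON, seed=0, ch4_fraction=0.0
        )
        assert out.emission_PgC_yr.iloc[0] == pytest.approx(1e-9, rel=1e-12)

    def test_missing_distribution_names_offending_stratum(self):
        inv = make_inventory(5, zone="sporadic")
        dists = make_dists(1.0)
        del dists[(Z.SPORADIC, BodyClass.RIVER)]
        with pytest.raises(InputError, match="sporadic"):
            upscale_inventory(inv, dists, UNIT_SEASON, seed=0)

    def test_conservation_total_equals_zone_and_class_sums(self):
        rng = np.random.default_rng(11)
        frames = [
            make_inventory(30, zone=z.value, body_class=c, area=a, lat=lat)
            for z, c, a, lat in [
                (Z.ABSENT, "river", 0.3, 58), (Z.ISOLATED, "lake", 1.2, 62),
                (Z.CONTINUOUS, "lake", 0.7, 70), (Z.SPORADIC, "river", 0.1, 64),
            ]
        ]
        inv = pd.concat(frames, ignore_index=True)
        out = upscale_inventory(inv, make_dists(2.0, sd=1.0), UNIT_SEASON, seed=9)
        total = out.emission_PgC_yr.sum()
        assert out.groupby("zone")["emission_PgC_yr"].sum().sum() == pytest.approx(total, rel=1e-12)
        assert out.groupby("body_class")["emission_PgC_yr"].sum().sum() == pytest.approx(total, rel=1e-12)

    def test_deterministic_under_seed(self):
        inv = make_inventory(100)
        a = upscale_inventory(inv, make_dists(2.0, sd=1.0), UNIT_SEASON, seed=5)
        b = upscale_inventory(inv, make_dists(2.0, sd=1.0), UNIT_SEASON, seed=5)
        assert a.equals(b)


def make_transect(pco2=390.0, n=50, zones=("absent",), ph=7.0, temp=15.0):
    frames = [
        pd.DataFrame(
            {"zone": z, "pCO2_uatm": np.full(n, pco2), "temp_C": np.full(n, temp),
             "pH": np.full(n, ph)}
        )
        for z in zones
    ]
    return pd.concat(frames, ignore_index=True)


class TestTransectUpscaling:
    def test_equilibrium_water_emits_nothing(self):
        tr = make_transect(pco2=390.0)
        out = upscale_transect(
            tr, {Z.ABSENT: 100.0}, {Z.ABSENT: 180.0},
            params=ExchangeParams(enhancement_enabled=False),
            n_draws=1000, seed=0, apply_spring_adjustment=False,
        )
        assert out.emission_PgC_yr.iloc[0] == pytest.approx(0.0, abs=1e-18)

    def test_missing_northern_zone_filled_from_southern_neighbour(self):
        tr = make_transect(pco2=1546.0, zones=("absent", "discontinuous"))
        out = upscale_transect(
            tr, {Z.DISCONTINUOUS: 50.0, Z.CONTINUOUS: 50.0},
            {Z.DISCONTINUOUS: 150.0, Z.CONTINUOUS: 150.0},
            n_draws=2000, seed=1,
        )
        rows = out.set_index("zone")
        assert rows.loc["continuous", "rate_mean_gC_m2_d"] == pytest.approx(
            rows.loc["discontinuous", "rate_mean_gC_m2_d"], rel=0.05
        )

    def test_unfillable_zone_rejected(self):
        tr = make_transect(zones=("discontinuous",))
        with pytest.raises(InputError):
            upscale_transect(tr, {Z.ABSENT: 10.0}, {Z.ABSENT: 100.0}, n_draws=100, seed=0)

    def test_monte_carlo_unbiased_vs_closed_form(self):
        # constant pH/temperature: the expectation is exactly
        # alpha * k * (K0 * (1.5*mean_pCO2 - 390)) in closed form
        from inlandcarbon.gas_exchange import bulk_co2_rate, enhancement_factor, add_ch4

        rng = np.random.default_rng(99)
        pco2 = rng.lognormal(7.2, 0.5, 400)
        tr = pd.DataFrame(
            {"zone": "absent", "pCO2_uatm": pco2, "temp_C": 15.0, "pH": 7.0}
        )
        params = ExchangeParams()
        n_draws = 100_000
        out = upscale_transect(
            tr, {Z.ABSENT: 1000.0}, {Z.ABSENT: 180.0},
            params=params, n_draws=n_draws, seed=4,
        )
        alpha = enhancement_factor(7.0, 15.0, params.k)
        closed = add_ch4(
            bulk_co2_rate(1.5 * pco2.mean(), 390.0, 15.0, params.k, alpha),
            params.ch4_fraction,
        )
        se = out.rate_sd_gC_m2_d.iloc[0] / np.sqrt(n_draws)
        assert abs(out.rate_mean_gC_m2_d.iloc[0] - closed) < 3 * se

    def test_two_seeds_agree_within_monte_carlo_error(self):
        rng = np.random.default_rng(12)
        tr = pd.DataFrame(
            {"zone": "absent", "pCO2_uatm": rng.lognormal(7.2, 0.53, 500),
             "temp_C": rng.normal(20, 2, 500), "pH": rng.uniform(6.5, 7.9, 500)}
        )
        kw = dict(n_draws=50_000)
        o1 = upscale_transect(tr, {Z.ABSENT: 100.0}, {Z.ABSENT: 180.0}, seed=1, **kw)
        o2 = upscale_transect(tr, {Z.ABSENT: 100.0}, {Z.ABSENT: 180.0}, seed=2, **kw)
        se = np.hypot(o1.rate_sd_gC_m2_d.iloc[0], o2.rate_sd_gC_m2_d.iloc[0]) / np.sqrt(
            kw["n_draws"]
        )
        assert abs(o1.rate_mean_gC_m2_d.iloc[0] - o2.rate_mean_gC_m2_d.iloc[0]) < 3 * se


class TestFixedRateAndYield:
    def test_stream_product_matches_hand_arithmetic(self):
        # 13,639 km2 x 5.67 g C m-2 d-1 x 180.6 d = 0.01397 Pg C yr-1
        assert upscale_fixed_rate(13_639, 5.67, 180.6) == pytest.approx(0.0139664, rel=1e-4)

    def test_zero_area_gives_zero(self):
        assert upscale_fixed_rate(0.0, 5.67, 180.6) == 0.0

    def test_linear_in_season(self):
        full = upscale_fixed_rate(100.0, 2.0, 180.0)
        half = upscale_fixed_rate(100.0, 2.0, 90.0)
        assert full == pytest.approx(2 * half, rel=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(DomainError):
            upscale_fixed_rate(-1.0, 5.67, 180.6)

    def test_yield_arithmetic(self):
        assert c_yield(0.001, 100_000.0) == pytest.approx(10.0, rel=1e-12)
        assert c_yield(0.0, 100_000.0) == 0.0

    def test_yield_zero_land_rejected(self):
        with pytest.raises(DomainError):
            c_yield(0.001, 0.0)


class TestFloodScenario:
    def zone_emissions(self):
        return pd.DataFrame(
            {
                "zone": ["absent", "isolated"],
                "body_class": ["river", "lake"],
                "emission_PgC_yr": [0.01, 0.02],
            }
        )

    def test_no_area_increase_no_change(self):
        assert floodplain_scenario(self.zone_emissions(), 180.6, area_increase=0.0) == 0.0

    def test_uniform_season_closed_form(self):
        # 0.85 x 30 / 180.6 = 14.12%
        pct = floodplain_scenario(self.zone_emissions(), 180.6)
        assert pct == pytest.approx(14.1196, abs=1e-3)

    def test_flood_longer_than_season_rejected(self):
        with pytest.raises(DomainError):
            floodplain_scenario(self.zone_emissions(), 20.0)

    def test_excluded_classes_contribute_no_increment(self):
        df = pd.DataFrame(
            {"zone": ["absent"], "body_class": ["pond"], "emission_PgC_yr": [0.05]}
        )
        assert floodplain_scenario(df, 180.6) == 0.0
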