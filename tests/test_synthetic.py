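"""Synthetic landscape generator: determinism, boundaries, calibration."""

import copy

import numpy as np
import pytest

from inlandcarbon.budget import aggregate_nee
from inlandcarbon.core import (
    ConfigurationError,
    LAKE_MIN_AREA_KM2,
    RIVER_MIN_WIDTH_M,
)
from inlandcarbon.size_distribution import fit_pareto_tail
from inlandcarbon.synthetic import (
    LandscapeConfig,
    generate_inventory,
    generate_nee_grid,
    generate_rate_observations,
    generate_transect,
)


class TestDeterminism:
    def test_inventory_bit_identical_under_fixed_seed(self, small_cfg):
        assert generate_inventory(small_cfg).equals(generate_inventory(small_cfg))

    def test_transect_bit_identical_under_fixed_seed(self, small_cfg):
        assert generate_transect(small_cfg).equals(generate_transect(small_cfg))

    def test_rate_observations_reproducible(self, small_cfg):
        assert generate_rate_observations(small_cfg).equals(
            generate_rate_observations(small_cfg)
        )

    def test_different_seeds_differ(self, small_cfg):
        other = small_cfg.replace(seed=8)
        assert not generate_inventory(small_cfg)["surface_area_km2"].equals(
            generate_inventory(other)["surface_area_km2"]
        )


class TestInventoryStructure:
    def test_class_boundaries_never_violated(self, small_cfg):
        inv = generate_inventory(small_cfg)
        rivers = inv[inv.body_class == "river"]
        lakes = inv[inv.body_class == "lake"]
        assert (rivers.width_m >= RIVER_MIN_WIDTH_M).all()
        assert (lakes.surface_area_km2 >= LAKE_MIN_AREA_KM2).all()
        assert (inv.surface_area_km2 > 0).all()
        assert inv.latitude.between(55, 73).all()

    def test_zero_stream_count_gives_only_bodies_above_cutoffs(self, small_cfg):
        inv = generate_inventory(small_cfg)
        assert "stream" not in set(inv.body_class.astype(str))
        assert "pond" not in set(inv.body_class.astype(str))

    def test_latitudes_respect_zone_bands(self, small_cfg):
        inv = generate_inventory(small_cfg)
        infos = small_cfg.zone_infos()
        for zone, info in infos.items():
            lats = inv.loc[inv.zone == zone.value, "latitude"]
            lo, hi = info.latitude_band
            assert lats.between(lo, hi).all()

    def test_lake_areas_refit_to_configured_shape(self, small_cfg):
        inv = generate_inventory(small_cfg)
        lakes = inv.loc[inv.body_class == "lake", "surface_area_km2"].to_numpy()
        fit = fit_pareto_tail(lakes, LAKE_MIN_AREA_KM2)
        assert fit.shape == pytest.approx(1.19, abs=0.05)

    def test_calibrated_lake_area_matches_published_inventory(self, full_inventory):
        lake_area = full_inventory.loc[
            full_inventory.body_class == "lake", "surface_area_km2"
        ].sum()
        assert lake_area == pytest.approx(171_029, rel=0.10)

    def test_calibrated_lotic_areas_match_published_inventory(self, full_inventory):
        river_area = full_inventory.loc[
            full_inventory.body_class == "river", "surface_area_km2"
        ].sum()
        mc_area = full_inventory.loc[
            full_inventory.body_class == "main_channel", "surface_area_km2"
        ].sum()
        assert river_area == pytest.approx(12_919, rel=0.10)
        assert mc_area == pytest.approx(6_831, rel=0.10)

    def test_negative_count_rejected(self, small_cfg):
        raw = copy.deepcopy(small_cfg.raw)
        raw["rivers"]["count"] = -5
        with pytest.raises(ConfigurationError):
            LandscapeConfig(raw)

    def test_nonpositive_shape_rejected(self, small_cfg):
        raw = copy.deepcopy(small_cfg.raw)
        raw["lakes"]["area_pareto"]["shape"] = 0.0
        with pytest.raises(ConfigurationError):
            LandscapeConfig(raw)


class TestTransect:
    def test_mean_converges_to_target(self, default_cfg):
        tr = generate_transect(default_cfg)
        n = len(tr)
        assert n == 4396
        se = 882.0 / np.sqrt(n)
        assert abs(tr.pCO2_uatm.mean() - 1546.0) < 3 * se

    def test_all_ph_below_eight(self, default_cfg):
        assert (generate_transect(default_cfg).pH < 8.0).all()

    def test_continuous_zone_intentionally_missing(self, default_cfg):
        zones = set(generate_transect(default_cfg).zone)
        assert "continuous" not in zones
        assert {"absent", "isolated", "sporadic", "discontinuous"} <= zones

    def test_zero_sd_gives_constant_series(self, small_cfg):
        raw = copy.deepcopy(small_cfg.raw)
        raw["transect"]["pCO2"]["sd_uatm"] = 0.0
        tr = generate_transect(LandscapeConfig(raw))
        assert tr.pCO2_uatm.nunique() == 1

    def test_positivity_violating_family_rejected(self, small_cfg):
        raw = copy.deepcopy(small_cfg.raw)
        raw["transect"]["pCO2"]["family"] = "normal"
        raw["transect"]["pCO2"]["sd_uatm"] = 2000.0
        with pytest.raises(ConfigurationError):
            LandscapeConfig(raw)


class TestRateObservations:
    def test_labelled_by_zone_and_class(self, default_cfg):
        obs = generate_rate_observations(default_cfg)
        assert set(obs.body_class) == {"river", "lake"}
        assert obs.groupby(["body_class"], observed=True).size()["river"] == 116

    def test_zero_mean_zero_sd_gives_all_zero(self, small_cfg):
        raw = copy.deepcopy(small_cfg.raw)
        for zone in raw["rates"]["river"]:
            raw["rates"]["river"][zone] = {"mean": 0.0, "sd": 0.0}
        obs = generate_rate_observations(LandscapeConfig(raw))
        assert (obs.loc[obs.body_class == "river", "rate_gC_m2_d"] == 0).all()

    def test_missing_zone_parameters_rejected(self, small_cfg):
        raw = copy.deepcopy(small_cfg.raw)
        del raw["rates"]["river"]["sporadic"]
        with pytest.raises(ConfigurationError):
            LandscapeConfig(raw).rate_params("river")

    def test_area_weighted_river_rate_near_published_annual(self, default_cfg):
        # configured rates x zone area shares x season -> ~0.9 kg C m-2 yr-1
        fracs = default_cfg.raw["rivers"]["zone_fractions"]
        intercept, slope = default_cfg.season_coefficients("river")
        annual = 0.0
        for zone, info in default_cfg.zone_infos().items():
            lo, hi = info.latitude_band
            season = intercept + slope * 0.5 * (lo + hi)
            mean, _ = default_cfg.rate_params("river")[zone]
            annual += fracs[zone.value] * mean * season
        assert annual / 1000.0 == pytest.approx(0.9, abs=0.2)


class TestNEEGeneration:
    def test_calibrated_grid_is_net_annual_sink(self, default_cfg):
        grid = generate_nee_grid(default_cfg)
        assert aggregate_nee(grid).value < 0

    def test_summer_uptake_exceeds_winter(self, default_cfg):
        grid = generate_nee_grid(default_cfg)
        daily = grid.data.groupby("day", observed=True)["rate_gC_m2_d"].mean()
        assert daily.loc[196] < 0 < daily.loc[1]

    def test_zero_configuration_gives_zero_total(self, small_cfg):
        raw = copy.deepcopy(small_cfg.raw)
        raw["nee"].update(
            winter_rate=0.0, summer_pulse_amplitude=0.0, cell_noise_sd=0.0,
            rate_sd_fraction=0.0, rate_sd_floor=0.0,
        )
        grid = generate_nee_grid(LandscapeConfig(raw))
        assert aggregate_nee(grid).value == 0.0

    def test_nonpositive_grid_rejected(self, small_cfg):
        raw = copy.deepcopy(small_cfg.raw)
        raw["nee"]["n_cells"] = 0
        with pytest.raises(ConfigurationError):
            LandscapeConfig(raw)

    def test_cell_resolution_carried(self, default_cfg):
        grid = generate_nee_grid(default_cfg)
        assert grid.cell_area_km2 == pytest.approx(8108.1)
        assert grid.n_days == 365
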