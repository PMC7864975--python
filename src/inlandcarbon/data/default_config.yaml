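# Calibrated default synthetic-landscape configuration.
#
# The generator emulates the statistical structure of the Western Siberian
# (Ob', Pur, Taz basins) inland-water inventory: truncated-Pareto river
# widths (shape 0.93) and lake areas (shape 1.19), a lognormal main-channel
# pCO2 series (mean 1546, s.d. 882 uatm), permafrost-zone-specific normal
# emission-rate distributions, and latitude-linear ice-free season lengths.
#
# CALIBRATED, NOT MEASURED: per-zone land areas, latitude bands, body
# counts and per-zone rate means/s.d. below are calibration constants
# chosen once so that the generated landscape reproduces the published
# aggregate inventory (class/zone surface-area totals, area-weighted
# annual emission rates of ~0.9 kg C m-2 yr-1 for rivers and ~0.2 for
# lakes, and a median river ice-free season of ~180.6 days).  They are not
# field measurements.
#
# Calibration notes:
#  * lake counts = target zone lake area / E[area] of the truncated
#    Pareto(1.19) on [0.01, 1000] km2 (E = 0.05560 km2)
#  * river/main-channel segment counts follow the source database row
#    counts (882,124 and 201,874); mean segment area = target class area /
#    count, split into width x length with E[width] = 407.8 m for the
#    truncated Pareto(0.93) on [90, 5500] m
#  * zone fractions place most main-channel and permafrost-free water in
#    the south, mirroring the real geography

seed: 12345

zones:
  absent:        {land_area_km2: 1340000.0, latitude_band: [55.0, 61.0]}
  isolated:      {land_area_km2:  440000.0, latitude_band: [61.0, 63.0]}
  sporadic:      {land_area_km2:  440000.0, latitude_band: [63.0, 65.0]}
  discontinuous: {land_area_km2:  640000.0, latitude_band: [65.0, 67.0]}
  continuous:    {land_area_km2:  740000.0, latitude_band: [67.0, 73.0]}

main_channel:
  count: 201874
  zone_fractions: {absent: 0.35, isolated: 0.30, sporadic: 0.15,
                   discontinuous: 0.10, continuous: 0.10}
  width_lognormal: {mean_m: 800.0, log_sd: 0.40}
  length_lognormal: {mean_m: 42.30, log_sd: 0.35}

rivers:
  count: 882124
  zone_fractions: {absent: 0.30, isolated: 0.15, sporadic: 0.15,
                   discontinuous: 0.20, continuous: 0.20}
  width_pareto: {shape: 0.93, min_m: 90.0, max_m: 5500.0}
  length_lognormal: {mean_m: 35.911, log_sd: 0.35}

streams:
  # streams enter the budget through Pareto extrapolation of the width
  # distribution, not as explicitly generated bodies
  count: 0
  width_pareto: {shape: 0.93, min_m: 0.32, max_m: 90.0}
  length_lognormal: {mean_m: 35.911, log_sd: 0.35}

lakes:
  zone_counts: {absent: 1347900, isolated: 259200, sporadic: 345700,
                discontinuous: 518500, continuous: 604900}
  area_pareto: {shape: 1.19, min_km2: 0.01, max_km2: 1000.0}

ponds:
  # ponds enter the budget through Pareto extrapolation (or the
  # land-fraction alternative), not as explicitly generated bodies
  zone_counts: {absent: 0, isolated: 0, sporadic: 0,
                discontinuous: 0, continuous: 0}
  area_pareto: {shape: 1.19, min_km2: 0.000115, max_km2: 0.01}

# Daily C emission rate distributions, g C m-2 d-1 (normal, per zone).
# CALIBRATED, NOT MEASURED (see header note).
rates:
  river:
    absent:        {mean: 4.5, sd: 2.5}
    isolated:      {mean: 6.5, sd: 3.0}
    sporadic:      {mean: 8.0, sd: 3.5}
    discontinuous: {mean: 8.0, sd: 3.5}
    continuous:    {mean: 5.5, sd: 3.0}
  lake:
    absent:        {mean: 0.6, sd: 0.3}
    isolated:      {mean: 1.3, sd: 0.7}
    sporadic:      {mean: 1.5, sd: 0.8}
    discontinuous: {mean: 2.1, sd: 1.0}
    continuous:    {mean: 2.3, sd: 1.1}

# Published fixed median rates used for the extrapolated size classes.
fixed_rates:
  stream: 5.67               # g C m-2 d-1, watersheds < 100 km2
  pond_permafrost: 1.12      # smallest permafrost-affected lakes
  pond_permafrost_free: 0.60 # smallest permafrost-free lakes

# Ice-free season length (days) = intercept + slope * latitude (deg N).
season_models:
  river: {intercept: 600.0, slope: -7.0}
  lake:  {intercept: 600.0, slope: -7.0}
stream_season_days: 180.6    # published median river season length

# Field-campaign emission-rate observation counts (sites concentrated in
# the south, so the median predicted river season is ~180.6 days).
field_sites:
  river_obs_per_zone: {absent: 70, isolated: 12, sporadic: 12,
                       discontinuous: 12, continuous: 10}
  lake_obs_per_zone:  {absent: 13, isolated: 40, sporadic: 50,
                       discontinuous: 68, continuous: 70}

# Main-channel underway pCO2 transect.  The ship never reached the
# continuous zone, so that zone is intentionally absent and downstream
# code must fill it from the adjacent discontinuous zone.
transect:
  n_per_zone: {absent: 1516, isolated: 1982, sporadic: 431,
               discontinuous: 467}
  pCO2: {mean_uatm: 1546.0, sd_uatm: 882.0, family: lognormal}
  pH: {mean: 7.2, sd: 0.4, max: 8.0}
  temp: {mean_C: 20.0, sd_C: 2.0}
  pressure: {mean_kPa: 101.3, sd_kPa: 1.0}

# Synthetic gridded daily NEE: full-region coverage at a reduced cell
# count (444 coarse cells x 8108.1 km2 ~ 3.6e6 km2 of land); the
# native 9 x 9 km product resolution remains usable via cell_area_km2.
nee:
  n_cells: 444
  cell_area_km2: 8108.1
  winter_rate: 0.35            # g C m-2 d-1 net respiration outside summer
  summer_pulse_amplitude: 1.436
  summer_pulse_day: 196
  summer_pulse_width_days: 45.0
  cell_noise_sd: 0.10
  rate_sd_fraction: 0.05
  rate_sd_floor: 0.02

# Riverine DOC + DIC export records (synthetic representative values,
# calibrated to the published regional total of 0.011 Pg C yr-1).
exports:
  - {river: "Ob", DOC_PgC_yr: 0.0046, DIC_PgC_yr: 0.0026}
  - {river: "Pur", DOC_PgC_yr: 0.0007, DIC_PgC_yr: 0.0007}
  - {river: "Taz", DOC_PgC_yr: 0.0012, DIC_PgC_yr: 0.0012}

kara_sea:
  mean_rate_mmol_m2_d: -7.64
  surface_area_km2: 926000.0   # standard geographic value for the Kara Sea
  days: 365

# Multiplies every body count; < 1 gives a down-scaled landscape for
# quick runs (aggregate areas shrink proportionally).
scale: 1.0
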