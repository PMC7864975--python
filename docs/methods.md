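# Methods

This note documents the models implemented in `inlandcarbon`, the
calibration of the default synthetic landscape, the numerical choices,
and what the test suite does and does not demonstrate about real data.

## 1. Gas exchange

The areal CO₂ flux uses the stagnant-film bulk model
`F = α k (C_w − C_eq)` with concentrations from Henry's law.

* **Solubility.** `K₀(T)` is the Weiss (1974) zero-salinity fit,
  `ln K₀ = −58.0931 + 90.5069 (100/T) + 22.2940 ln(T/100)` in
  mol L⁻¹ atm⁻¹ (T in kelvin), valid −1…40 °C and strictly decreasing in
  temperature. Requests outside that range raise a domain error. The
  10⁻⁶ factor in the flux equation is the µatm→atm conversion and lives
  inside the Henry's-law step; all fluxes are carried internally in
  g C m⁻² d⁻¹ via the 12.011 g mol⁻¹ molar mass of carbon.
* **Chemical enhancement.** The classical Hoover & Berkshire (1969)
  boundary-layer hydration model:
  `α = τ / [(τ − 1) + tanh(Q)/Q]`, `Q = √(r τ D) / k`,
  where `τ = 1 + [H⁺]²/(K₁[H⁺] + K₁K₂)` (acidic water ⇒ τ → ∞ ⇒ α → 1;
  alkaline water ⇒ τ → 1 ⇒ α → Q/tanh Q), `r = k_CO₂ + k_OH·[OH⁻]` is the
  combined hydration rate (Johnson 1982 for `k_CO₂`; `k_OH` anchored at
  8,500 M⁻¹ s⁻¹ at 25 °C with an Arrhenius slope of ~52 kJ mol⁻¹ — its
  contribution is <5% of `r` at pH < 8, so the approximation is
  immaterial), and `D` is CO₂ diffusivity (1.92×10⁻⁹ m² s⁻¹ at 25 °C,
  Arrhenius). Carbonate constants are the freshwater Harned fits. The
  model is exposed behind `enhancement_enabled` so the flux equation can
  also run with α forced to 1; at the regional median k = 4.464 m d⁻¹ and
  pH < 8 the enhancement is small (α ≈ 1.003–1.01). Note α is *not*
  applied per-system k estimation — k enters as a measured constant.
* **pH truncation.** The flux path requires pH < 8 (observed river pH
  never exceeded 8); `enhancement_factor` enforces this as a
  precondition and callers truncate at 7.999.
* **CH₄ share semantics.** "1.19% CH₄ in C emission" is read as a share
  of the *total*: `total = CO₂ / (1 − f)`, so CH₄ is exactly f of the
  output. At f = 0.0119 this differs from a (1 + f) markup by <0.02%,
  but the contract is fixed and tested. The published lake and pond
  rates already include diffusive CH₄, so the share is added only to
  main-channel and river CO₂ rates.
* **Seasonal adjustment.** Ship transect pCO₂ represents summer; spring
  pCO₂ is approximated as twice summer, and the open-water effective
  value is their average (×1.5). Applied to the water-side pCO₂ only.

## 2. Size distributions and area extrapolation

Observed tails are modelled as Pareto: `N(>x) = c·x^(−β)`.

* **Fitting.** The maximum-likelihood (Hill) estimator on exceedances,
  `β̂ = n / Σ ln(xᵢ/x_min)`, with the scale anchored so the fitted
  exceedance count at the cutoff equals the observed count. Shapes are
  also directly settable, since published basin-specific shapes exist
  (0.93 for river widths, 1.19 for lake areas). The pipeline *fits* the
  lake-area tail (the truncation of the generated sample at 1,000 km²
  biases Hill by only ~10⁻⁵) but *sets* the width shape to 0.93: on a
  width sample truncated at 5,500 m the Hill estimator is biased by
  ~+0.09, and the original shape was itself a literature value.
* **Extrapolation.** Count and summed size on [physical minimum, cutoff)
  are closed-form integrals of size × number density
  (`∫ x · cβx^(−β−1) dx`), with the logarithmic branch at β = 1, checked
  against numerical quadrature at 10⁻⁶ relative tolerance. For β < 1 the
  area integral is dominated by the large end, for β > 1 by the small
  end — both regimes are regression-tested.
* **Stream area.** Width databases carry no area below the 90 m cutoff.
  The contract: area per width class ∝ width × number density,
  normalised so the tail integral over [90 m, max observed width]
  equals the observed river area (rivers only, excluding the main
  channel, whose widths are not Pareto). This is isolated in one
  function so alternative width→area closures can be swapped in.
* **Pond alternative.** Fixed land fractions from satellite pond
  inventories: 2.9% of land in the permafrost-free/isolated/sporadic
  zones, 0.62% in discontinuous/continuous. Under the calibrated
  defaults the Pareto pond term is ~3.4-fold larger than this
  alternative, bracketing the total budget.
* **Shape uncertainty.** Published shape s.d. (±0.0004) and
  physical-minimum uncertainties propagate through the uniform 15%
  convention of the uncertainty module rather than analytic
  sensitivities, matching the budget's uniform treatment.

## 3. Upscaling

* **Rate pools.** Per zone and class, 10,000 normal deviates are
  pre-generated from the configured (mean, s.d.) and re-sampled per water
  body — faithful to the original re-sampling structure rather than
  drawing fresh normals. Negative draws are retained (net uptake is
  admissible); truncation at zero is switchable
  (`RateDistribution(truncate_negative=True)`).
* **Season.** Ice-free days = intercept + slope × latitude, fitted by
  least squares to synthetic season observations at the field-site
  latitudes (true line + 4 d noise, R² ≈ 0.98, mirroring the published
  river R² = 0.99 and lake R² = 0.96 fits). Streams use the fixed
  published median of 180.6 d; ponds use the median lake season of their
  zone. The fitted model is checked for positivity across 55–73 °N.
* **Main channel.** Per zone, 100,000 Monte Carlo draws resample pCO₂,
  pH and temperature independently from the transect observations (the
  original procedure resampled the variables independently); each draw
  runs the flux equation with enhancement and median k. The continuous
  zone carries no samples (the ship stopped short) and is filled from
  the adjacent discontinuous zone — implemented generically as
  "nearest sampled zone to the south".
* **Units audit.** 1 g C m⁻² d⁻¹ over 1 km² for 1 day is exactly
  10⁻⁹ Pg; an end-to-end test asserts this, and all conversions happen
  only inside operations (module boundaries are km², g C m⁻² d⁻¹, days,
  Pg C yr⁻¹).
* **Flood scenario.** A spring flood adds `area_increase × area` for
  `flood_days` at each zone's mean daily rate:
  `extra_z = E_z · 0.85 · 30 / season_z`, restricted to lotic + lake
  classes (ponds excluded — the flooding concerns floodplains and
  wetlands). With a single season of 180.6 d the closed form is +14.1%;
  with per-zone seasons the calibrated default gives ≈ +17%. The
  published ~11% is not recoverable from the stated 85%/30-day
  assumption with any single season length; both numbers are reported
  side by side rather than tuned.

## 4. Uncertainty and statistics

* The product rule `δR = |R|·√(Σ(δxᵢ/xᵢ)²)` with 15% on rates, areas
  and season lengths gives √3 × 15% ≈ 26.0% on every component; sums
  combine in quadrature `δ = √(Σδᵢ²)`. (The multiplicative form is the
  standard rule; it reproduces every published ± cell, which an additive
  `|R| + √(…)` reading cannot.)
* The main-channel Monte Carlo spread re-samples 10 batches of 1,000
  values of each input pool; with a right-skewed pCO₂ pool the batch
  mean exceeds the batch median (direction reproduced; the magnitude is
  data-dependent).
* Kruskal–Wallis across zones uses scipy's tie-corrected H on values
  subsampled without replacement to 500 per zone (recorded seed), with
  the χ² reference (group sizes are in the hundreds; no exact
  small-sample tables). Null type-I error is verified at ≈5% over 5,000
  simulated replicates.

## 5. Regional budget

* Annual NEE = Σ_days Σ_cells rate × cell area; per-cell-day standard
  deviations combine in quadrature. Incomplete cell-day coverage is an
  error unless explicitly allowed.
* Sea uptake = rate (mmol m⁻² d⁻¹) × 10⁻³ × 12.011 × days × area /
  10¹⁵. The Kara Sea surface area (9.26×10⁵ km²) is a named config
  entry (a standard geographic value; the source analysis does not print
  it).
* Ratios are computed from the pipeline's own emission bracket
  (land-fraction pond total, Pareto pond total); the published ranges
  were evidently computed on unrounded intermediates, so computed
  intervals are reported as such, alongside the inputs.

## 6. The synthetic landscape and its calibration

The generator emulates the *statistical* structure the analysis
assumes — not the geography. Key choices:

* **Lotic geometry.** Databases report short raster-derived segments;
  counts follow the source row counts (201,874 main-channel and 882,124
  river segments). Each segment's area is width × length with lognormal
  lengths (the analysis never uses lengths; this closure keeps class
  areas calibratable). Widths: truncated Pareto(0.93) on [90, 5500] m
  for rivers; lognormal (mean 800 m) for the main channel.
* **Lakes.** Truncated Pareto(1.19) on [0.01, 1000] km²; zone counts =
  target zone lake area / E[area] = 0.0556 km². The 1,000 km² upper
  truncation reflects the largest lakes of such lowlands and keeps the
  sample-total variance finite (β < 2 would otherwise give wild
  run-to-run totals).
* **Zones and latitudes.** Five latitude bands (55–61, 61–63, 63–65,
  65–67, 67–73 °N) with uniform within-band latitudes; land areas sum
  to 3.6×10⁶ km². Bands are plumbing for the season model, not
  geography.
* **Transect.** Lognormal pCO₂ moment-matched to mean 1546 / s.d. 882
  µatm (positivity; the distribution family is not stated in the source)
  with the published per-zone sample counts (1516, 1982, 431, 467) and
  no continuous-zone samples; pH truncated-normal below 8; water
  temperature 20 ± 2 °C (mid-summer main-channel conditions).
* **Rates.** Per-zone normal (mean, s.d.) for rivers and lakes are
  **calibrated, not measured** (the field values live in a supplement
  that is not reproduced here): they were chosen once so that the
  area-weighted annual rates land near 0.9 (rivers) and 0.2
  (lakes) kg C m⁻² yr⁻¹, the per-component budget matches the published
  table, and the C yield peaks in the discontinuous zone. They follow
  the published qualitative pattern (hump-shaped across the gradient for
  rivers, increasing with permafrost extent for lakes).
* **NEE.** Full-region coverage at 444 coarse cells × 8,108 km² (not
  71,280 × 81 km²; same total area, far smaller tables); daily rate =
  +0.35 g C m⁻² d⁻¹ winter respiration minus a Gaussian summer uptake
  pulse (amplitude 1.436, day 196, width 45 d), giving ≈ −34 g C m⁻²
  yr⁻¹ and an annual total of ≈ −0.11 Pg C. Only the *sign and order*
  of the regional NEE are meaningful on synthetic data — the real value
  (−0.198 Pg C yr⁻¹) requires the satellite product.
* **Scale knob.** `scale` multiplies water-body counts for quick runs;
  zone *land* areas are deliberately not scaled, so land-fraction pond
  areas and yields are only comparable to the published numbers at
  `scale = 1`.

**What passing tests show.** That the implementation reproduces the
published arithmetic exactly where the inputs are printed (uncertainty
algebra, sea uptake, fixed-rate products), and reproduces the published
budget within its printed uncertainties when fed a landscape with the
*assumed* statistical structure. They do not validate the statistical
assumptions themselves (Pareto pond behaviour is known to be doubtful —
hence the bracketing alternative), nor rate transferability across real
geography, nor any temporal variability beyond the spring adjustment
and flood scenario.

## 7. Known numerical deltas (documented, not failures)

* Stream fixed-rate product: 13,639 km² × 5.67 g C m⁻² d⁻¹ × 180.6 d =
  0.0140 Pg, vs 0.013 printed (≈7%; within the printed ±0.003 either
  way). The package reports its own arithmetic.
* Flood scenario: +14.1% closed form (single season) / ≈ +17% per-zone,
  vs ~11% printed (basis unstated).
* Published headline ranges (35–50%, 2.4–3.0×, 6.8–9.0×) derive from
  unrounded intermediates; computed intervals from the rounded printed
  components differ slightly (e.g. 6.9–9.5×) and are reported as
  computed.

## 8. Problem sizes and determinism

The default configuration generates ~4.16 M water bodies, a 4,396-sample
transect, 357 rate observations and a 162,060-row NEE table; a full
pipeline run takes ~10 s on one CPU. All randomness flows from a single
master seed through fixed per-product stream keys (inventory 1, transect
2, rates 3, NEE 4, pools 5, upscaling 6, season fit 8, subsampling 9),
so any product can be regenerated in isolation, and identical config +
seed yields byte-identical CSV/YAML outputs. The run manifest (seed,
config hash, package version, method switches) suffices to reproduce a
report exactly.
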