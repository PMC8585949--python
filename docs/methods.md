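# Methods

This note documents the models, parameter choices and calibrations behind
`sahelcc`, and what the synthetic domain does and does not represent.

## Synthetic domain

The domain is an abstract grid of equal-area cells (default 12,100 ha each,
matching a 0.1° cell near the equator; no coordinates, since geography plays
no role in the accounting). A configurable fraction — default 0.12/0.90, the
two-zone share of the study region — is Sahelian, the rest Sudanian.

**Land use.** Per-cell fractions of grass/crop/tree/settlement/other are
Dirichlet draws around zone means (Sahel 70/10/10/2/8%, Sudan 45/30/17/3/5%,
concentration 40), renormalized to the simplex; crop shares within cropland
(maize/millet/sorghum/groundnut) likewise (Sahel millet-dominated, Sudan more
balanced). Woody cover is Beta-distributed with zone means 2% and 5%. These
dispersion parameters are free choices: observed products constrain zone means
but the cell-level covariance is not published, so spatial heterogeneity is a
generator parameter rather than data.

**Climate.** Monthly rainfall is a fixed zone weight vector — Sahel nonzero
June–September (0.22/0.28/0.28/0.22), Sudan May–October
(0.10/0.16/0.24/0.24/0.16/0.10) — scaled to an annual total
`(MAP_cell + b·(year − midpoint)) · lognormal noise`. The weights put 3–4
months above the 50-mm wet-month threshold at Sahel normals and 6 at Sudanian
normals, and keep every wet month clear of the threshold across the reference
trend range so the noise-free wet-season length is stable. Per-cell mean
annual precipitation spreads lognormally around the zone normal (σ = 0.10);
interannual noise is lognormal (σ = 0.15, mean-one) and temperature noise
additive Gaussian (σ = 0.3 °C). With noise off all dispersion vanishes and
zone means are exact. Trends are anchored at the midpoint of the year range,
so they do not change the period mean — and a relative-linear trend is
recovered *exactly* by the Sen-slope/mean trend metric (below).

**Livestock.** Spatial weights per species are one Dirichlet draw over cells
(α = 2, giving realistic heterogeneity in stocking density) held fixed over
time, mirroring products that scale a single reference distribution; totals
grow geometrically at a per-decade rate from the first year.

The generators emulate statistical structure only: no spatial autocorrelation,
no drought persistence, no land-use change over time, no transhumance. Passing
tests therefore validate the accounting and trend machinery under controlled
structure, not any data-driven regional result.

## Biomass surrogate

Process-based biomass simulation is out of scope; a rain-use-efficiency (RUE)
model preserves the causal chain rainfall → dry matter → energy that the trend
analysis needs:

* forage: `RUE_zone · P_annual · frac_grass`, RUE 0.408 (Sahel) and 0.90
  (Sudan) kg DM ha⁻¹ mm⁻¹, back-solved from zone production means of 0.1 and
  0.6 t ha⁻¹ on pure grassland at zone-normal rainfall;
* cereal residues: `RUE_crop,zone · P_annual · frac_crop · crop_share`, RUE
  1.118/1.568 kg DM ha⁻¹ mm⁻¹ back-solved so the *total* zone means hit
  0.1/0.6 t ha⁻¹ given the mean land-use composition; split 60:40 into stem
  and leaf (the split is not a published value — only per-part proper-use and
  ME are — so it is a configurable placeholder);
* groundnut residue: whole-plant;
* browse: produced directly as digestible DM, 65 (Sahel) and 135 (Sudan)
  kg ha⁻¹ at a reference woody cover of 0.5, scaled by `woody_cover/0.5`;
  rainfall-independent.

Forage and residues carry mean-one lognormal model noise (σ = 0.10 default).
The harvest month is the month after the last wet month; seasons classify a
month as wet at ≥ 50 mm, with `wet_days = round(30.42 · n_wet)`.

## Energy supply

`usable = DM · proper_use · ME_avg`, with forage additionally × 1.076 (grazing
uplift) and residues × `(1 − 0.08)^months` storage decay. Decay is compounded
rather than linear — "8% per month" on a remaining stock naturally compounds,
and over ≤ 8 months the difference is < 4%. The min/avg/max ME columns support
an optional uncertainty band (`me_band`); the central pipeline uses averages.
Season allocation: 80% of forage energy to the wet season (standing hay
carries the rest), browse proportional to season day counts, residues entirely
dry-season with decay evaluated at the dry-season midpoint
(`dry_days/30.42/2` months). This allocation is pipeline plumbing — only its
annual sum is constrained (wet + dry = annual holds exactly).

## Herd energy demand

The maintenance form `K·Sx·M·(0.26·W^0.75·e^(−0.03A))/k_m` with
`k_m = 0.02·ME + 0.5`, growth `ADG·17/k_g` with `k_g = 0.042·ME + 0.006`,
lactation `milk·3.1/0.6` and locomotion `2.6 kJ·W·km/k_m` follow the CSIRO
ruminant-requirement conventions. Function defaults are K = 1.2, Sx = M = 1;
the shipped herd file sets K = 1.1 for zebu cattle (tropical breeds run
10–20% below the 1.4 B. taurus standard) and 1.0 for small ruminants. Diet ME
densities are the zone forage averages (6.1/6.5 MJ kg⁻¹). Dry season: cattle
lose 12% of bodyweight and mature small ruminants 22% — implemented as a
season-mean effective weight `W·(1 − loss/2)` plus a mobilization credit
`W·loss·28 MJ·0.84` subtracted from the seasonal total and floored at zero;
immature small ruminants instead gain 30% less per day. Thermoregulation and
pregnancy are excluded.

Herd shares, weights, ages, gains, milk and walking distances are regional
plumbing defaults, not measurements; they were calibrated **once, before the
test suite was written**, so that the herd-average demand per TLU falls inside
the FAO-consistency band of 8,000–12,000 MJ TLU⁻¹ yr⁻¹ (≈ 1.5–2.5% of
bodyweight as daily DM intake). The `W^0.75` scaling makes young stock and
small ruminants expensive per TLU, so this band constrains the defaults
materially: light travel (2/4 km cattle, 1.5/3 small ruminants), modest gains
(0.04–0.10 kg d⁻¹), 0.5 kg d⁻¹ milk, adult ages of 6 (cattle) and 3 years,
and a cattle-leaning species mix (1 : 0.6 : 0.8 cattle : sheep : goat by
head). The realized herd average is ≈ 11,700 MJ TLU⁻¹ yr⁻¹.

## Balance and aggregation

`S/D` per cell-year (+∞ when D = 0 < S; undefined and excluded when both are
0). LCC divides supply by the same cell-year's demand per TLU (zone-year mean
for unstocked cells; 9,400 MJ TLU⁻¹ yr⁻¹ as the last-resort constant).
Regional series are reported under both readings of a "regional S/D" —
`ΣS/ΣD` (default) and the area-weighted mean of finite cell ratios — since
either is defensible; the deficit-area fraction is the area share of cells
whose period-mean ratio is below 1, and the decadal summary covers 1981–1990
through 2011–2020 (partial decades compute with a warning).

## Trend statistics

Mann–Kendall S with the standard tie-corrected variance, ±1 continuity
correction and two-sided normal p; Theil–Sen median pairwise slope as the
magnitude estimator (robust and consistent with the rank test); relative
trends reported as `10·sen/mean·100` percent per decade. The indices use
population (not sample) SD — the 12 months are the complete annual cycle —
and the precipitation-seasonality divisor is `1 + mean(monthly)` (the
coefficient-of-variation convention; a literal `1 + sum` variant is available
behind a flag).

## Reference-scenario calibration

The shipped scenario (`paper_default`) imposes the study conditions as
generator settings: supply trending −9%/decade domain-wide but +3.4%/decade
in the Sahelian zone, demand +37%/decade, and a 1981 regional S/D of 2.6. The
calibration (`sahelcc/calibrate.py`) is solved analytically on archetype cells
(zone-mean composition, noise off) using the pipeline's own supply and demand
functions, not fitted to output:

* supply responds affinely to annual rainfall, so the zone precipitation
  trends (mm yr⁻¹, midpoint-anchored) follow in closed form from the target
  percent-per-decade values — Sahel +0.85 mm yr⁻¹, Sudan −6.38 mm yr⁻¹ with
  the default parameters;
* demand grows geometrically, and the Sen/mean metric reads *less* than the
  nominal compound rate on a convex series (a nominal 37%/decade measures
  ≈ 30 over 40 years); the nominal rate is therefore root-found so the
  measured trend is 37%/decade (nominal ≈ 48.8%/decade);
* base livestock densities scale so that first-year regional `ΣS/ΣD` is 2.6.

Under these conditions the regional ratio crosses 1.0 in 2001–2002 and the
decadal deficit-area fraction rises strictly (≈ 16 → 29 → 56 → 81%). Problem
sizes of 500 cells × 40 years keep every run deterministic-per-seed and fast
(a few seconds).

## Known limitations

* The biomass surrogate is linear in rainfall: no water-use saturation, soil
  effects, CO₂ or management response; zone calibration holds only near the
  default land-use means.
* Herd demography is exogenous — no births/deaths feedback, no destocking
  response to deficit, no feed trade or mobility between cells.
* Per-category seasonal requirements bracket plausible West African values
  but do not reproduce any specific published herd parameterization.
* Statistical tests are per-series; no field-significance or multiple-testing
  control across cells.
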