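# sahelcc

Livestock carrying-capacity accounting for Sahelian and Sudanian rangelands:
a tested, seeded pipeline that balances feed-**energy supply** against herd
**energy demand** on a gridded domain and quantifies how that balance trends
over decades.

## The problem and the model

Agro-pastoral systems in the West African drylands feed their herds from three
resources: natural pasture, browse (edible shrub/tree foliage) and crop
residues. Whether an area can sustain its herd is a question of energy
accounting. For each grid cell and year the package computes

* **Supply** `S` (MJ ME): dry-matter production per feed class, converted with
  metabolizable-energy contents (ME, MJ per kg DM) and *proper-use* fractions —
  the share of each resource that can be taken without degrading it (55% for
  pasture; 0.70 × 0.55 ≈ 0.38 for browse; 10–100% for residue parts). Managed
  rotational grazing raises pasture output by 7.6%; stored residues lose 8% of
  their nutritive value per month after harvest.
* **Demand** `D` (MJ ME): species headcounts are split into herd categories
  (cattle: bull/steer/calf/heifer/cow; sheep and goats: young/mature), each
  with CSIRO-style seasonal requirements for maintenance
  (`K·Sx·0.26·W^0.75·e^(−0.03A)/k_m`), growth, lactation and locomotion. In the
  dry season cattle lose ~12% of bodyweight (mature small ruminants 22%) and
  the mobilized tissue energy is credited against the requirement.
* **Balance**: the ratio `S/D` (< 1 marks a feed deficit), the deficit-area
  fraction, and the **livestock carrying capacity**
  `LCC = S / MER_TLU / area` in Tropical Livestock Units
  (`TLU = Σ_j (MLW_j/250) · HS_j · N`) per hectare.
* **Trends**: Mann–Kendall tests (tie-corrected, continuity-corrected) with
  Theil–Sen slopes reported as percent of the series mean per decade, plus
  three bioclimatic indices (temperature seasonality, precipitation
  seasonality, De Martonne aridity).

Real gridded climate/livestock/biomass products are out of scope; a seeded
synthetic-data module generates a domain with the right statistical structure
(zone split, seasonal rainfall shapes, land-use composition, geometric herd
growth, configurable trends), and a rain-use-efficiency surrogate maps annual
rainfall to dry matter per feed class. See `docs/methods.md` for assumptions
and calibration.

## Worked example

```sh
python examples/04_regional_balance_trends.py
```

runs the calibrated reference scenario (300 cells, 1981–2020, seeded noise)
and prints:

```
regional S/D: 2.60 (1981) -> 0.40 (2019), first deficit year 2001

decadal summary:
   decade  regional_sd  deficit_area_pct
1981-1990         2.08             16.33
1991-2000         1.30             29.67
2001-2010         0.79             53.67
2011-2020         0.48             79.00

trends (Theil-Sen, % of mean per decade; Mann-Kendall p):
  supply_total           -9.22 %/decade   p=3.96e-18
  demand_total          +36.87 %/decade   p=1.12e-19
  sd_ratio_of_totals    -43.87 %/decade   p=1.12e-19
  supply_sahelian        +3.91 %/decade   p=1.71e-09
  supply_sudanian        -9.55 %/decade   p=3.22e-18

mean carrying capacity: 0.15 TLU/ha
```

The region starts with a 2.6-fold energy surplus, demand growth (+37%/decade)
and shrinking supply (−9%/decade, though +3.4%/decade in the wetter-trending
Sahel) push the ratio below 1 around the millennium, and the share of area in
deficit rises every decade. The other examples walk through the domain
generator, the feed-to-energy arithmetic and the herd demand model one step
at a time.

A thin CLI wraps the same library calls:

```sh
sahelcc run --reference --seed 5 --cells 500 --out myrun   # everything + manifest
sahelcc report --dir myrun                                 # decadal table, crossing year
sahelcc simulate / supply / demand / balance / trends      # stage by stage
```

All I/O is plain CSV; `manifest.json` records the config hash, seed and a
checksum per artifact, and a rerun with the same config is byte-identical.

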