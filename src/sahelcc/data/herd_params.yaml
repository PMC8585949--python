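# Herd structure and CSIRO-style energy-requirement parameters.
#
# Herd shares, live weights, gains, milk yields and walking distances are regional
# plumbing defaults for West African agro-pastoral herds (zebu cattle, Sahelian
# sheep/goats), calibrated so the herd-average requirement per Tropical Livestock
# Unit sits near 10^4 MJ/yr — the FAO-consistent intake of 1.5-2% of bodyweight.
# They are not measured values for any particular herd.
#
# Maintenance: MER_M = K * Sx * M * 0.26 * W^0.75 * exp(-0.03*A) / k_m,
#   k_m = 0.02*ME_diet + 0.5.  K (species_factor): 1.1 for zebu cattle
#   (~10-20% below the B. taurus standard of 1.4), 1.0 for small ruminants.
# Growth:      MER_G = ADG * 17 / k_g, k_g = 0.042*ME_diet + 0.006
# Lactation:   MER_L = milk * 3.1 / 0.6
# Locomotion:  MER_T = 2.6e-3 * W * km_walked / k_m
#
# Dry-season bodyweight loss: cattle 12%, mature small ruminants 22% (season-mean
# effective weight W*(1 - loss/2)); mobilized tissue (28 MJ/kg at 0.84 efficiency)
# is credited against the seasonal total, floored at zero. Immature small
# ruminants gain 30% less in the dry season instead of losing weight.
energy:
  energy_per_kg_gain: 17.0   # MJ per kg liveweight gain
  milk_energy_mj_kg: 3.1     # MJ per kg milk
  k_lactation: 0.6
  walk_cost_kj_kg_km: 2.6
  tissue_energy_mj_kg: 28.0  # energy density of mobilized body tissue
  mobilization_efficiency: 0.84
  cattle_dry_weight_loss: 0.12
  small_ruminant_adult_dry_weight_loss: 0.22
  immature_dry_adg_factor: 0.7   # dry-season ADG of immature small ruminants
diet_me_mj_kg:                   # zone forage averages used for k_m / k_g
  sahelian: 6.1
  sudanian: 6.5
species:
  cattle:
    species_factor: 1.1
    dry_weight_loss: cattle
    categories:
      - {name: bull,   share: 0.05, mlw_kg: 350, age_yr: 6.0, adg_wet: 0.00, adg_dry: 0.0, milk_wet: 0.0, milk_dry: 0.0, dist_wet_km: 2.0, dist_dry_km: 4.0, sex_multiplier: 1.15, mature_female: false}
      - {name: steer,  share: 0.10, mlw_kg: 270, age_yr: 3.0, adg_wet: 0.08, adg_dry: 0.0, milk_wet: 0.0, milk_dry: 0.0, dist_wet_km: 2.0, dist_dry_km: 4.0, sex_multiplier: 1.0, mature_female: false}
      - {name: calf,   share: 0.20, mlw_kg: 100, age_yr: 0.5, adg_wet: 0.10, adg_dry: 0.0, milk_wet: 0.0, milk_dry: 0.0, dist_wet_km: 1.5, dist_dry_km: 3.0, sex_multiplier: 1.0, mature_female: false}
      - {name: heifer, share: 0.20, mlw_kg: 200, age_yr: 3.0, adg_wet: 0.08, adg_dry: 0.0, milk_wet: 0.0, milk_dry: 0.0, dist_wet_km: 2.0, dist_dry_km: 4.0, sex_multiplier: 1.0, mature_female: false}
      - {name: cow,    share: 0.45, mlw_kg: 250, age_yr: 6.0, adg_wet: 0.00, adg_dry: 0.0, milk_wet: 0.5, milk_dry: 0.1, dist_wet_km: 2.0, dist_dry_km: 4.0, sex_multiplier: 1.0, mature_female: true}
  sheep:
    species_factor: 1.0
    dry_weight_loss: small_ruminant
    categories:
      - {name: young,  share: 0.30, mlw_kg: 20, age_yr: 0.5, adg_wet: 0.04, adg_dry: null, milk_wet: 0.0, milk_dry: 0.0, dist_wet_km: 1.5, dist_dry_km: 3.0, sex_multiplier: 1.0, mature_female: false}
      - {name: mature, share: 0.70, mlw_kg: 35, age_yr: 3.0, adg_wet: 0.00, adg_dry: 0.0, milk_wet: 0.1, milk_dry: 0.0, dist_wet_km: 1.5, dist_dry_km: 3.0, sex_multiplier: 1.0, mature_female: true}
  goat:
    species_factor: 1.0
    dry_weight_loss: small_ruminant
    categories:
      - {name: young,  share: 0.30, mlw_kg: 18, age_yr: 0.5, adg_wet: 0.04, adg_dry: null, milk_wet: 0.0, milk_dry: 0.0, dist_wet_km: 1.5, dist_dry_km: 3.0, sex_multiplier: 1.0, mature_female: false}
      - {name: mature, share: 0.70, mlw_kg: 30, age_yr: 3.0, adg_wet: 0.00, adg_dry: 0.0, milk_wet: 0.1, milk_dry: 0.0, dist_wet_km: 1.5, dist_dry_km: 3.0, sex_multiplier: 1.0, mature_female: true}
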