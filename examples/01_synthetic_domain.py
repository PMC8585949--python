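"""Build a small synthetic domain and look at its climate structure.

Generates 100 grid cells split ~13/87 between the Sahelian and Sudanian zones
and a noise-free monthly climate, then prints the zone-mean annual rainfall,
temperature and wet-season length.  The numbers should echo the zone normals:
~245 mm / 29 degC with a 3-4 month wet season in the Sahel, ~670 mm / 28 degC
with a 5-7 month wet season in the Sudanian zone.
"""
from sahelcc import DomainConfig, build_domain, classify_seasons, generate_climate

cfg = DomainConfig(n_cells=100, seed=11, climate_noise=False)
cells = build_domain(cfg)
climate = generate_climate(cells, range(1981, 2021), cfg)
seasons = classify_seasons(climate)

annual = climate.groupby(["cell_id", "year"])["precip_mm"].sum().groupby("cell_id").mean()
tmean = climate.groupby("cell_id")["tmean_c"].mean()
summary = cells.set_index("cell_id").assign(
    map_mm=annual, mat_c=tmean, wet_months=seasons.groupby("cell_id")["n_wet_months"].mean()
)
print(summary.groupby("zone")[["map_mm", "mat_c", "wet_months", "frac_grass", "frac_crop"]].mean().round(2))
print(f"\ncells: {len(cells)}  (sahelian: {(cells.zone == 'sahelian').sum()})")
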