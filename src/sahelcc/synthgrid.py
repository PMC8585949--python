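"""Seeded synthetic domain: grid cells, monthly climate, livestock counts.

The generators emulate the statistical structure of the gridded inputs the
analysis assumes: a fixed split of equal-area cells between the Sahelian and
Sudanian zones, unimodal monthly rainfall scaled to annual totals with
configurable linear trends and lognormal interannual noise, and species
headcounts whose spatial distribution is drawn once and held fixed while the
totals grow geometrically.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (
    CROPS,
    CROP_SHARE_MEANS,
    LANDUSE_MEANS,
    MONTHLY_PRECIP_WEIGHTS,
    MONTHLY_TEMP_OFFSETS,
    SAHELIAN,
    SPECIES,
    SUDANIAN,
    DomainConfig,
    WOODY_COVER_MEANS,
    substream,
)

LANDUSE_COLS = ["frac_grass", "frac_crop", "frac_tree", "frac_settlement", "frac_other"]
CROP_SHARE_COLS = [f"share_{c}" for c in CROPS]


def build_domain(config: DomainConfig) -> pd.DataFrame:
    """Generate the cell table: zones, areas, land-use fractions, woody cover.

    The first ``round(n_cells * sahel_fraction)`` cells are Sahelian, the rest
    Sudanian.  Land-use fractions are Dirichlet draws around the zone means and
    renormalized to sum to exactly 1; crop shares likewise within cropland.
    """
    n = config.n_cells
    n_sahel = int(round(n * config.sahel_fraction))
    zones = np.array([SAHELIAN] * n_sahel + [SUDANIAN] * (n - n_sahel))
    rng = substream(config.seed, "domain")

    frames = []
    for zone in (SAHELIAN, SUDANIAN):
        idx = np.flatnonzero(zones == zone)
        if idx.size == 0:
            continue
        lu_means = np.array([LANDUSE_MEANS[zone][k] for k in ("grass", "crop", "tree", "settlement", "other")])
        lu = rng.dirichlet(lu_means * config.landuse_concentration, size=idx.size)
        lu /= lu.sum(axis=1, keepdims=True)
        cs_means = np.array([CROP_SHARE_MEANS[zone][c] for c in CROPS])
        cs = rng.dirichlet(cs_means * config.crop_share_concentration, size=idx.size)
        cs /= cs.sum(axis=1, keepdims=True)
        m = WOODY_COVER_MEANS[zone]
        k = config.woody_cover_concentration
        woody = rng.beta(m * k, (1 - m) * k, size=idx.size)
        df = pd.DataFrame(lu, columns=LANDUSE_COLS)
        df[CROP_SHARE_COLS] = cs
        df["woody_cover"] = woody
        df.insert(0, "zone", zone)
        df.insert(0, "cell_id", idx)
        frames.append(df)

    cells = pd.concat(frames, ignore_index=True).sort_values("cell_id", ignore_index=True)
    cells.insert(2, "area_ha", float(config.area_ha))
    return cells


def generate_climate(cells: pd.DataFrame, years, config: DomainConfig) -> pd.DataFrame:
    """Monthly precipitation and temperature per cell-year.

    Annual precipitation for a cell is ``(MAP_cell + trend * (year - midpoint))``
    times lognormal interannual noise, distributed over months by the fixed
    zone profile; temperature is the zone normal plus a fixed seasonal cycle, a
    linear warming trend and additive noise.  With ``climate_noise`` off the
    per-cell dispersion and all noise vanish and zone means are exact.
    """
    years = np.asarray(list(years), dtype=int)
    if years.size == 0:
        raise ValueError("empty year range")
    y_mid = years.mean()
    rng = substream(config.seed, "climate")

    n = len(cells)
    zone_arr = cells["zone"].to_numpy()
    recs = []
    for zone in (SAHELIAN, SUDANIAN):
        mask = zone_arr == zone
        nz = int(mask.sum())
        if nz == 0:
            continue
        zc = config.climate[zone]
        weights = np.asarray(MONTHLY_PRECIP_WEIGHTS[zone])
        if config.climate_noise:
            s = config.map_dispersion_sigma
            map_cell = zc.map_mm * rng.lognormal(-0.5 * s * s, s, size=nz)
            annual_noise = rng.lognormal(
                -0.5 * config.precip_noise_sigma**2, config.precip_noise_sigma, size=(nz, years.size)
            )
            temp_noise = rng.normal(0.0, config.temp_noise_sigma, size=(nz, years.size, 12))
        else:
            map_cell = np.full(nz, zc.map_mm)
            annual_noise = np.ones((nz, years.size))
            temp_noise = np.zeros((nz, years.size, 12))

        annual = (map_cell[:, None] + zc.precip_trend_mm_yr * (years - y_mid)[None, :]) * annual_noise
        annual = np.clip(annual, 0.0, None)
        precip = annual[:, :, None] * weights[None, None, :]
        tmean = (
            zc.mat_c
            + np.asarray(MONTHLY_TEMP_OFFSETS)[None, None, :]
            + (zc.warming_c_per_40yr / 40.0) * (years - y_mid)[None, :, None]
            + temp_noise
        )

        cell_ids = cells.loc[mask, "cell_id"].to_numpy()
        ii, yy, mm = np.meshgrid(np.arange(nz), np.arange(years.size), np.arange(12), indexing="ij")
        recs.append(
            pd.DataFrame(
                {
                    "cell_id": cell_ids[ii.ravel()],
                    "year": years[yy.ravel()],
                    "month": mm.ravel() + 1,
                    "precip_mm": precip.ravel(),
                    "tmean_c": tmean.ravel(),
                }
            )
        )
    out = pd.concat(recs, ignore_index=True)
    return out.sort_values(["cell_id", "year", "month"], ignore_index=True)


def generate_livestock(cells: pd.DataFrame, years, config: DomainConfig) -> pd.DataFrame:
    """Headcounts per cell, year and species.

    Spatial weights per species are a single Dirichlet draw over cells (the
    relative distribution is constant through time); species totals grow
    geometrically at the configured per-decade rate from the first year.
    """
    years = np.asarray(list(years), dtype=int)
    if years.size == 0:
        raise ValueError("empty year range")
    rng = substream(config.seed, "livestock")
    n = len(cells)
    total_area = float(cells["area_ha"].sum())
    y0 = years.min()

    frames = []
    for sp in SPECIES:
        weights = rng.dirichlet(np.full(n, config.livestock_dirichlet_alpha))
        base_total = config.base_density_per_ha.get(sp, 0.0) * total_area
        growth = config.growth_per_decade.get(sp, 0.0)
        totals = base_total * (1.0 + growth) ** ((years - y0) / 10.0)
        counts = weights[:, None] * totals[None, :]
        ii, yy = np.meshgrid(np.arange(n), np.arange(years.size), indexing="ij")
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": cells["cell_id"].to_numpy()[ii.ravel()],
                    "year": years[yy.ravel()],
                    "species": sp,
                    "headcount": counts.ravel(),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["species", "cell_id", "year"], ignore_index=True)
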