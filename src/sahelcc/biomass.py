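"""Rain-use-efficiency biomass surrogate and wet/dry season classification.

Dry-matter production per feed class is modelled as a linear response to annual
precipitation (rain-use efficiency, kg DM ha-1 mm-1) scaled by the land-use
fraction that produces it, which preserves the climate-to-biomass causal
pathway the trend analysis needs.  Browse foliage is produced directly as
digestible dry matter at a zone rate referenced to a standard woody cover.
Default efficiencies are calibrated so that noise-free zone-mean total
production is ~0.1 t ha-1 (Sahelian) and ~0.6 t ha-1 (Sudanian).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CROPS, SAHELIAN, SUDANIAN, substream

DAYS_PER_MONTH = 30.42
CEREALS = ("maize", "millet", "sorghum")
FEED_CLASSES = (
    "forage",
    "browse",
    "residue_maize",
    "residue_millet",
    "residue_sorghum",
    "residue_groundnut",
)


@dataclass
class BiomassParams:
    """Rain-use efficiencies and browse rates of the biomass surrogate.

    ``rue_forage`` are back-solved from the published zone production means
    (0.1 t ha-1 at 245 mm, 0.6 t ha-1 at 670 mm on pure grassland); ``rue_crop``
    from the zone totals once the mean land-use composition is fixed.  Browse
    ``foliage_kg_ha`` is digestible DM per hectare at ``reference_cover`` woody
    cover.  ``stem_fraction`` splits cereal residue mass into stem vs leaf.
    """

    rue_forage: dict = field(default_factory=lambda: {SAHELIAN: 100.0 / 245.0, SUDANIAN: 0.90})
    rue_crop: dict = field(default_factory=lambda: {SAHELIAN: 1.118, SUDANIAN: 1.568})
    foliage_kg_ha: dict = field(default_factory=lambda: {SAHELIAN: 65.0, SUDANIAN: 135.0})
    reference_cover: float = 0.5
    stem_fraction: float = 0.6
    noise_sigma: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 <= self.stem_fraction <= 1.0:
            raise ValueError("stem_fraction must lie in [0, 1]")
        if self.reference_cover <= 0:
            raise ValueError("reference_cover must be positive")


def classify_seasons(climate: pd.DataFrame, wet_month_threshold_mm: float = 50.0) -> pd.DataFrame:
    """Wet/dry season mask per cell-year.

    A month is wet iff its precipitation is at least the threshold (default
    50 mm); wet days are ``30.42 * n_wet`` rounded and dry days the complement
    of 365.  Also reports the first/last wet month and the residue harvest
    month (month after the wet season ends).
    """
    counts = climate.groupby(["cell_id", "year"])["month"].count()
    if (counts != 12).any():
        bad = counts[counts != 12].index.tolist()[:5]
        raise ValueError(f"each cell-year needs exactly 12 monthly values; offenders include {bad}")

    cl = climate.sort_values(["cell_id", "year", "month"])
    wet = cl["precip_mm"].to_numpy() >= wet_month_threshold_mm
    months = cl["month"].to_numpy()
    wide = wet.reshape(-1, 12)
    mo = months.reshape(-1, 12)
    keys = cl[["cell_id", "year"]].iloc[::12].reset_index(drop=True)

    n_wet = wide.sum(axis=1)
    wet_days = np.rint(DAYS_PER_MONTH * n_wet).astype(int)
    wet_days = np.minimum(wet_days, 365)
    first = np.where(n_wet > 0, np.where(wide, mo, 99).min(axis=1), 0)
    last = np.where(n_wet > 0, np.where(wide, mo, 0).max(axis=1), 0)
    harvest = np.where(last == 0, 11, last % 12 + 1)

    out = keys.copy()
    out["n_wet_months"] = n_wet
    out["first_wet_month"] = first
    out["last_wet_month"] = last
    out["wet_days"] = wet_days
    out["dry_days"] = 365 - wet_days
    out["harvest_month"] = harvest
    return out


def simulate_biomass(
    cells: pd.DataFrame,
    climate: pd.DataFrame,
    params: BiomassParams | None = None,
    seed: int = 0,
    noise: bool = True,
    seasons: pd.DataFrame | None = None,
    wet_month_threshold_mm: float = 50.0,
) -> pd.DataFrame:
    """Dry-matter production per cell, year, feed class and plant part.

    forage  : RUE_zone * annual precip * frac_grass
    residue : RUE_crop,zone * annual precip * frac_crop * crop_share,
              cereals split stem/leaf by ``stem_fraction``, groundnut whole
    browse  : foliage rate * (woody_cover / reference_cover), precip-independent

    Forage and residues get multiplicative lognormal noise (mean one) when
    ``noise`` is on.  Output ``dm_kg_ha`` is per hectare of the whole cell.
    """
    params = params or BiomassParams()
    if seasons is None:
        seasons = classify_seasons(climate, wet_month_threshold_mm)

    annual = climate.groupby(["cell_id", "year"], as_index=False)["precip_mm"].sum()
    annual = annual.rename(columns={"precip_mm": "annual_precip_mm"})
    base = annual.merge(
        cells[["cell_id", "zone", "frac_grass", "frac_crop", "woody_cover"]
              + [f"share_{c}" for c in CROPS]],
        on="cell_id",
        how="left",
        validate="many_to_one",
    )
    base = base.merge(seasons[["cell_id", "year", "harvest_month"]], on=["cell_id", "year"])
    rng = substream(seed, "biomass")
    nrow = len(base)

    def jitter() -> np.ndarray:
        if not noise or params.noise_sigma <= 0:
            return np.ones(nrow)
        s = params.noise_sigma
        return rng.lognormal(-0.5 * s * s, s, size=nrow)

    rue_f = base["zone"].map(params.rue_forage).to_numpy()
    rue_c = base["zone"].map(params.rue_crop).to_numpy()
    foliage = base["zone"].map(params.foliage_kg_ha).to_numpy()
    precip = base["annual_precip_mm"].to_numpy()

    frames = []

    def emit(feed_class: str, part: str, dm: np.ndarray, with_harvest: bool) -> None:
        df = base[["cell_id", "year"]].copy()
        df["feed_class"] = feed_class
        df["part"] = part
        df["dm_kg_ha"] = np.clip(dm, 0.0, None)
        df["harvest_month"] = base["harvest_month"] if with_harvest else 0
        frames.append(df)

    emit("forage", "whole", rue_f * precip * base["frac_grass"].to_numpy() * jitter(), False)
    emit("browse", "whole", foliage * base["woody_cover"].to_numpy() / params.reference_cover, False)
    for crop in CROPS:
        dm = rue_c * precip * base["frac_crop"].to_numpy() * base[f"share_{crop}"].to_numpy() * jitter()
        if crop == "groundnut":
            emit("residue_groundnut", "whole", dm, True)
        else:
            emit(f"residue_{crop}", "stem", dm * params.stem_fraction, True)
            emit(f"residue_{crop}", "leaf", dm * (1.0 - params.stem_fraction), True)

    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["cell_id", "year", "feed_class", "part"], ignore_index=True)
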