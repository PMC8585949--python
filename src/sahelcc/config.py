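"""Domain and pipeline configuration.

The synthetic domain is an abstract grid of equal-area cells split between the
Sahelian belt (short June-September wet season, mean annual precipitation around
245 mm, mean annual temperature around 29 degC) and the Sudanian zone (wet season
mainly May-October, around 670 mm and 28 degC).  All structural choices that the
generators need -- land-use composition, monthly rainfall shape, interannual
noise, livestock densities and growth -- live here so that one seeded config
reproduces the whole pipeline.
"""
from __future__ import annotations

import dataclasses
import hashlib
import zlib
from dataclasses import dataclass, field

import numpy as np
import yaml

SAHELIAN = "sahelian"
SUDANIAN = "sudanian"
ZONES = (SAHELIAN, SUDANIAN)
SPECIES = ("cattle", "sheep", "goat")
CROPS = ("maize", "millet", "sorghum", "groundnut")

#: Monthly rainfall weights (Jan..Dec).  Sahelian rain falls June-September with
#: a July-August peak; Sudanian rain is spread May-October.  At the zone-mean
#: annual totals these shapes put 3-4 (Sahel) and 5-7 (Sudan) months above the
#: 50 mm wet-month threshold.
MONTHLY_PRECIP_WEIGHTS = {
    SAHELIAN: (0.0, 0.0, 0.0, 0.0, 0.0, 0.22, 0.28, 0.28, 0.22, 0.0, 0.0, 0.0),
    SUDANIAN: (0.0, 0.0, 0.0, 0.0, 0.10, 0.16, 0.24, 0.24, 0.16, 0.10, 0.0, 0.0),
}

#: Monthly temperature offsets (degC, zero mean) around the annual mean: hot
#: pre-monsoon (April-May), mild harmattan season (December-January).
MONTHLY_TEMP_OFFSETS = (-5.0, -2.0, 1.0, 4.0, 5.0, 4.0, 1.0, -1.0, 0.0, 1.0, -2.0, -6.0)
assert abs(sum(MONTHLY_TEMP_OFFSETS)) < 1e-9

#: Mean land-use composition per zone (grass, crop, tree, settlement, other).
LANDUSE_MEANS = {
    SAHELIAN: {"grass": 0.70, "crop": 0.10, "tree": 0.10, "settlement": 0.02, "other": 0.08},
    SUDANIAN: {"grass": 0.45, "crop": 0.30, "tree": 0.17, "settlement": 0.03, "other": 0.05},
}

#: Mean share of each crop within cropland per zone.
CROP_SHARE_MEANS = {
    SAHELIAN: {"maize": 0.05, "millet": 0.60, "sorghum": 0.25, "groundnut": 0.10},
    SUDANIAN: {"maize": 0.25, "millet": 0.30, "sorghum": 0.30, "groundnut": 0.15},
}

WOODY_COVER_MEANS = {SAHELIAN: 0.02, SUDANIAN: 0.05}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible RNG substream derived from a single integer seed."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


@dataclass
class ZoneClimate:
    """Climate normals and imposed trends for one agro-ecological zone."""

    map_mm: float
    mat_c: float
    precip_trend_mm_yr: float = 0.0
    warming_c_per_40yr: float = 0.0


@dataclass
class DomainConfig:
    """Everything the synthetic-domain generators need.

    Trends are anchored at the midpoint of the simulated year range so that the
    period means equal the configured normals; ``sahel_fraction`` defaults to the
    two-zone share 0.12 / (0.12 + 0.78) of the study region.
    """

    n_cells: int = 500
    sahel_fraction: float = 0.12 / 0.90
    area_ha: float = 12_100.0
    seed: int = 0
    climate: dict[str, ZoneClimate] = field(
        default_factory=lambda: {
            SAHELIAN: ZoneClimate(map_mm=245.0, mat_c=29.0),
            SUDANIAN: ZoneClimate(map_mm=670.0, mat_c=28.0),
        }
    )
    climate_noise: bool = True
    map_dispersion_sigma: float = 0.10      # lognormal sigma of per-cell MAP spread
    precip_noise_sigma: float = 0.15        # lognormal sigma of interannual totals
    temp_noise_sigma: float = 0.3           # degC, additive monthly noise
    landuse_concentration: float = 40.0     # Dirichlet concentration of land-use draws
    crop_share_concentration: float = 30.0
    woody_cover_concentration: float = 50.0
    base_density_per_ha: dict[str, float] = field(
        default_factory=lambda: {"cattle": 0.040, "sheep": 0.024, "goat": 0.032}
    )
    growth_per_decade: dict[str, float] = field(
        default_factory=lambda: {"cattle": 0.37, "sheep": 0.37, "goat": 0.37}
    )
    livestock_dirichlet_alpha: float = 2.0  # spatial concentration of herd weights

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")
        if not 0.0 <= self.sahel_fraction <= 1.0:
            raise ValueError(f"sahel_fraction must lie in [0, 1], got {self.sahel_fraction}")
        if self.area_ha <= 0:
            raise ValueError("area_ha must be positive")
        for sp, d in self.base_density_per_ha.items():
            if d < 0:
                raise ValueError(f"negative base density for {sp}")


@dataclass
class PipelineConfig:
    """One run of the full pipeline: domain, years, parameter files, outputs."""

    domain: DomainConfig = field(default_factory=DomainConfig)
    years: tuple[int, int] = (1981, 2020)
    out_dir: str = "sahelcc_run"
    feed_params_path: str | None = None   # None -> packaged Table-1 defaults
    herd_params_path: str | None = None   # None -> packaged herd defaults
    wet_forage_share: float = 0.8
    wet_month_threshold_mm: float = 50.0
    regional_method: str = "ratio_of_totals"
    me_band: bool = False                 # also run with me_min / me_max
    biomass_noise_sigma: float = 0.10
    write_breakdown: bool = True

    def __post_init__(self) -> None:
        y0, y1 = self.years
        if not (1900 <= y0 <= y1 <= 2100):
            raise ValueError(f"years must be an increasing range within 1900-2100, got {self.years}")
        if self.regional_method not in ("ratio_of_totals", "mean_of_ratios"):
            raise ValueError(f"unknown regional method {self.regional_method!r}")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def config_to_yaml(cfg: PipelineConfig) -> str:
    return yaml.safe_dump(_to_plain(cfg), sort_keys=True)


def config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(config_to_yaml(cfg).encode("utf-8")).hexdigest()


def config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    dom = dict(d.pop("domain", {}))
    if "climate" in dom:
        dom["climate"] = {z: ZoneClimate(**zc) for z, zc in dom["climate"].items()}
    if "years" in d:
        d["years"] = tuple(d["years"])
    return PipelineConfig(domain=DomainConfig(**dom), **d)


def load_config(path: str) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return config_from_dict(yaml.safe_load(fh) or {})
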