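"""End-to-end pipeline orchestration: generate, account, balance, test trends.

Stages run in a fixed order (domain -> climate -> livestock -> seasons ->
biomass -> supply -> demand -> balance -> trends); every output is a plain CSV
and a manifest records the config hash, seed and a checksum per file so that a
rerun with the same config can be verified byte-for-byte.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import balance as bl
from . import biomass as bm
from . import demand as dm
from . import metrics as mt
from . import supply as sp
from . import synthgrid as sg
from .config import SAHELIAN, SUDANIAN, PipelineConfig, config_hash

logger = logging.getLogger("sahelcc")

FLOAT_FORMAT = "%.10g"


class PipelineStageError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def _write(df: pd.DataFrame, path: Path) -> dict:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    return {"rows": int(len(df)), "sha256": digest}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage, write all artifacts, return the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    feed = sp.FeedParams.from_yaml(cfg.feed_params_path) if cfg.feed_params_path else sp.FeedParams.default()
    herd = dm.HerdParams.from_yaml(cfg.herd_params_path) if cfg.herd_params_path else dm.HerdParams.default()

    manifest: dict = {
        "config_sha256": config_hash(cfg),
        "seed": cfg.domain.seed,
        "files": {},
        "timings_s": {},
        "complete": False,
    }
    artifacts: dict[str, pd.DataFrame] = {}

    def stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            manifest["failed_stage"] = name
            raise PipelineStageError(name, exc) from exc
        manifest["timings_s"][name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %-10s %6.2fs", name, manifest["timings_s"][name])
        return result

    years = cfg.year_list
    cells = stage("domain", lambda: sg.build_domain(cfg.domain))
    climate = stage("climate", lambda: sg.generate_climate(cells, years, cfg.domain))
    livestock = stage("livestock", lambda: sg.generate_livestock(cells, years, cfg.domain))
    seasons = stage("seasons", lambda: bm.classify_seasons(climate, cfg.wet_month_threshold_mm))
    biomass = stage(
        "biomass",
        lambda: bm.simulate_biomass(
            cells,
            climate,
            bm.BiomassParams(noise_sigma=cfg.biomass_noise_sigma),
            seed=cfg.domain.seed,
            noise=cfg.biomass_noise_sigma > 0,
            seasons=seasons,
        ),
    )
    supply = stage(
        "supply",
        lambda: sp.cell_supply(biomass, cells, seasons, feed, wet_forage_share=cfg.wet_forage_share),
    )
    demand, breakdown = stage(
        "demand",
        lambda: dm.cell_demand(livestock, herd, seasons, cells, with_breakdown=cfg.write_breakdown),
    )
    balance = stage("balance", lambda: bl.cell_balance(sp.total_supply(supply), demand, cells))
    regional = stage("regional", lambda: bl.regional_sd(balance))
    decades = stage("decades", lambda: bl.decadal_summary(balance))

    def trends() -> pd.DataFrame:
        by_zone = balance.groupby(["zone", "year"])["s_mj"].sum().unstack(0)
        series = {
            "supply_total": balance.groupby("year")["s_mj"].sum(),
            "demand_total": balance.groupby("year")["d_mj"].sum(),
            "sd_ratio_of_totals": regional.set_index("year")["ratio_of_totals"],
        }
        for zone in (SAHELIAN, SUDANIAN):
            if zone in by_zone:
                series[f"supply_{zone}"] = by_zone[zone]
        return mt.trend_table(series)

    trend_df = stage("trends", trends)
    bioclim = stage("bioclim", lambda: mt.bioclim_table(climate))

    if cfg.me_band:
        for label in ("min", "max"):
            s_band = sp.cell_supply(biomass, cells, seasons, feed, cfg.wet_forage_share, me=label)
            band_balance = bl.cell_balance(sp.total_supply(s_band), demand, cells)
            artifacts[f"regional_sd_me_{label}"] = bl.regional_sd(band_balance)

    artifacts.update(
        cells=cells,
        climate=climate,
        livestock=livestock,
        seasons=seasons,
        biomass=biomass,
        supply=supply,
        demand=demand,
        balance=balance,
        regional_sd=regional,
        decadal_summary=decades,
        trends=trend_df,
        bioclim=bioclim,
    )
    if breakdown is not None:
        artifacts["mer_breakdown"] = breakdown

    for name, df in artifacts.items():
        manifest["files"][f"{name}.csv"] = stage(f"write:{name}", lambda d=df, n=name: _write(d, out / f"{n}.csv"))
    manifest["complete"] = True
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def load_artifacts(out_dir: str, names=("cells", "balance", "regional_sd", "decadal_summary", "trends")) -> dict:
    """Read previously written pipeline CSVs back into DataFrames."""
    out = Path(out_dir)
    found = {}
    for n in names:
        p = out / f"{n}.csv"
        if not p.exists():
            raise FileNotFoundError(f"missing pipeline artifact: {p}")
        found[n] = pd.read_csv(p)
    return found


def first_deficit_year(regional: pd.DataFrame, method: str = "ratio_of_totals") -> int | None:
    """First year in which the regional S/D drops below 1."""
    below = regional.loc[regional[method] < 1.0, "year"]
    return int(below.min()) if len(below) else None
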