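"""Herd energy demand: CSIRO-style metabolizable-energy requirements and TLU.

Species headcounts are split into age/sex categories by fixed herd shares;
each category has seasonal requirements for maintenance, growth, lactation and
locomotion.  Dry-season bodyweight loss (12% for cattle, 22% for mature small
ruminants) lowers the effective weight and credits mobilized tissue energy
against the seasonal total, floored at zero; immature small ruminants instead
gain 30% less per day.  Demand is aggregated per cell-year together with the
herd expressed in Tropical Livestock Units (250 kg reference animal):

    TLU = sum_j (MLW_j / 250) * HS_j * N_species
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

TLU_REFERENCE_KG = 250.0


@dataclass
class HerdParams:
    """Herd structure plus the energy coefficients, as one parameter set."""

    species: dict
    energy: dict
    diet_me_mj_kg: dict

    @classmethod
    def default(cls) -> "HerdParams":
        with resources.files("sahelcc.data").joinpath("herd_params.yaml").open("r") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def from_yaml(cls, path: str) -> "HerdParams":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def from_dict(cls, raw: dict) -> "HerdParams":
        for sp, spec in raw["species"].items():
            total = sum(c["share"] for c in spec["categories"])
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"category shares for {sp} sum to {total}, expected 1")
            for c in spec["categories"]:
                if c["mlw_kg"] <= 0:
                    raise ValueError(f"non-positive live weight in {sp}/{c['name']}")
        return cls(species=raw["species"], energy=raw["energy"], diet_me_mj_kg=raw["diet_me_mj_kg"])

    def tlu_per_head(self, species: str) -> float:
        return sum(
            c["share"] * c["mlw_kg"] / TLU_REFERENCE_KG for c in self.species[species]["categories"]
        )


def k_maintenance(diet_me_mj_kg: float) -> float:
    """Efficiency of ME use for maintenance, k_m = 0.02 ME + 0.5."""
    return 0.02 * diet_me_mj_kg + 0.5


def k_growth(diet_me_mj_kg: float) -> float:
    """Efficiency of ME use for gain, k_g = 0.042 ME + 0.006."""
    return 0.042 * diet_me_mj_kg + 0.006


def mer_maintenance(
    weight_kg: float,
    age_yr: float,
    sex_multiplier: float = 1.0,
    species_factor: float = 1.2,
    diet_me_mj_kg: float = 6.5,
    milk_adjustment: float = 1.0,
) -> float:
    """Daily maintenance requirement, MJ ME day-1.

    K * Sx * M * (0.26 * W^0.75 * exp(-0.03 A)) / k_m.
    """
    w = np.asarray(weight_kg, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weight_kg must be positive")
    if diet_me_mj_kg <= 0:
        raise ValueError("diet ME must be positive")
    out = (
        species_factor
        * sex_multiplier
        * milk_adjustment
        * 0.26
        * w**0.75
        * np.exp(-0.03 * np.asarray(age_yr, dtype=float))
        / k_maintenance(diet_me_mj_kg)
    )
    return float(out) if out.ndim == 0 else out


def mer_growth(adg_kg_day: float, energy_per_kg_gain: float = 17.0, diet_me_mj_kg: float = 6.5) -> float:
    """Daily growth requirement, MJ ME day-1: ADG * E_gain / k_g."""
    adg = np.asarray(adg_kg_day, dtype=float)
    if np.any(adg < 0):
        raise ValueError("adg_kg_day must be >= 0")
    out = adg * energy_per_kg_gain / k_growth(diet_me_mj_kg)
    return float(out) if out.ndim == 0 else out


def mer_lactation(milk_kg_day: float, milk_energy_mj_kg: float = 3.1, k_l: float = 0.6) -> float:
    """Daily lactation requirement, MJ ME day-1: milk * E_milk / k_l."""
    if k_l <= 0:
        raise ValueError("k_l must be positive")
    milk = np.asarray(milk_kg_day, dtype=float)
    if np.any(milk < 0):
        raise ValueError("milk_kg_day must be >= 0")
    out = milk * milk_energy_mj_kg / k_l
    return float(out) if out.ndim == 0 else out


def mer_travel(
    weight_kg: float,
    distance_km_day: float,
    walk_cost_kj_kg_km: float = 2.6,
    diet_me_mj_kg: float = 6.5,
) -> float:
    """Daily locomotion requirement, MJ ME day-1: (cost/1000) * W * d / k_m."""
    d = np.asarray(distance_km_day, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance_km_day must be >= 0")
    out = (walk_cost_kj_kg_km / 1000.0) * np.asarray(weight_kg, float) * d / k_maintenance(diet_me_mj_kg)
    return float(out) if out.ndim == 0 else out


def _category_season(herd: HerdParams, species: str, cat: dict, season: str, zone: str) -> dict:
    """Daily MER components and seasonal mobilization credit for one category."""
    if season not in ("wet", "dry"):
        raise ValueError(f"unknown season {season!r}")
    en = herd.energy
    spec = herd.species[species]
    me = herd.diet_me_mj_kg[zone]
    K = spec.get("species_factor", 1.2)

    mlw = cat["mlw_kg"]
    if season == "wet":
        weight = mlw
        loss = 0.0
        adg = cat["adg_wet"]
        milk = cat["milk_wet"]
        dist = cat["dist_wet_km"]
    else:
        if spec.get("dry_weight_loss") == "cattle":
            loss = en["cattle_dry_weight_loss"]
        elif cat.get("mature_female") or cat["name"] == "mature":
            loss = en["small_ruminant_adult_dry_weight_loss"]
        else:
            loss = 0.0
        weight = mlw * (1.0 - loss / 2.0)  # season-mean effective weight
        adg = cat.get("adg_dry")
        if adg is None:
            adg = en["immature_dry_adg_factor"] * cat["adg_wet"]
        milk = cat["milk_dry"]
        dist = cat["dist_dry_km"]

    m = mer_maintenance(weight, cat["age_yr"], cat.get("sex_multiplier", 1.0), K, me)
    g = mer_growth(adg, en["energy_per_kg_gain"], me)
    lact = mer_lactation(milk, en["milk_energy_mj_kg"], en["k_lactation"]) if milk > 0 else 0.0
    t = mer_travel(weight, dist, en["walk_cost_kj_kg_km"], me)
    credit = mlw * loss * en["tissue_energy_mj_kg"] * en["mobilization_efficiency"]
    return {"daily_m": m, "daily_g": g, "daily_l": lact, "daily_t": t, "credit": credit}


def seasonal_category_demand(
    herd: HerdParams, species: str, category: str, season: str, season_days: float, zone: str
) -> dict:
    """Per-animal seasonal MER breakdown (MJ per season), floored at zero."""
    if not 0 <= season_days <= 365:
        raise ValueError("season_days must lie in [0, 365]")
    cat = next(c for c in herd.species[species]["categories"] if c["name"] == category)
    r = _category_season(herd, species, cat, season, zone)
    comp = {k.replace("daily_", "mer_"): v * season_days for k, v in r.items() if k.startswith("daily")}
    credit = r["credit"] if season == "dry" else 0.0
    total = max(0.0, sum(comp.values()) - credit)
    return {**comp, "mobilization_credit": credit, "mer_total": total}


def rate_table(herd: HerdParams, zones=("sahelian", "sudanian")) -> pd.DataFrame:
    """Daily MER components and credits per (zone, species, category, season)."""
    rows = []
    for zone in zones:
        for sp, spec in herd.species.items():
            for cat in spec["categories"]:
                for season in ("wet", "dry"):
                    r = _category_season(herd, sp, cat, season, zone)
                    rows.append(
                        {"zone": zone, "species": sp, "category": cat["name"], "season": season,
                         "share": cat["share"], "mlw_kg": cat["mlw_kg"],
                         **r, "credit": r["credit"] if season == "dry" else 0.0}
                    )
    return pd.DataFrame(rows)


def split_herd(livestock: pd.DataFrame, herd: HerdParams) -> pd.DataFrame:
    """Category headcounts: species headcount times herd share (sum conserved)."""
    unknown = set(livestock["species"]) - set(herd.species)
    if unknown:
        raise KeyError(f"unknown species in livestock table: {sorted(unknown)}")
    shares = pd.DataFrame(
        [
            {"species": sp, "category": c["name"], "share": c["share"]}
            for sp, spec in herd.species.items()
            for c in spec["categories"]
        ]
    )
    out = livestock.merge(shares, on="species")
    out["headcount"] = out["headcount"] * out["share"]
    return out.drop(columns="share")


def compute_tlu(livestock: pd.DataFrame, herd: HerdParams) -> pd.DataFrame:
    """Tropical livestock units per cell-year from species headcounts."""
    tlu_head = livestock["species"].map({sp: herd.tlu_per_head(sp) for sp in herd.species})
    df = livestock.assign(tlu=livestock["headcount"] * tlu_head)
    return df.groupby(["cell_id", "year"], as_index=False)["tlu"].sum()


def cell_demand(
    livestock: pd.DataFrame,
    herd: HerdParams,
    seasons: pd.DataFrame,
    cells: pd.DataFrame,
    with_breakdown: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Total demand D (MJ), TLU and demand per TLU, per cell-year.

    Returns ``(demand, breakdown)``; the breakdown lists per-animal seasonal
    MER components and the herd total per (cell, year, species, category,
    season).  Demand is the share-weighted headcount times the floored
    seasonal per-animal total, summed over categories and seasons.
    """
    need = livestock[["cell_id", "year"]].drop_duplicates()
    have = seasons[["cell_id", "year"]].drop_duplicates()
    missing = need.merge(have, on=["cell_id", "year"], how="left", indicator=True)
    missing = missing[missing["_merge"] == "left_only"]
    if len(missing):
        raise ValueError(
            f"missing season mask for cell-years like {missing[['cell_id', 'year']].head().to_records(index=False).tolist()}"
        )

    rates = rate_table(herd, zones=sorted(cells["zone"].unique()))
    df = livestock.merge(cells[["cell_id", "zone"]], on="cell_id", validate="many_to_one")
    df = df.merge(seasons[["cell_id", "year", "wet_days", "dry_days"]], on=["cell_id", "year"])
    df = df.merge(rates, on=["zone", "species"])
    days = np.where(df["season"] == "wet", df["wet_days"], df["dry_days"])
    for comp in ("m", "g", "l", "t"):
        df[f"mer_{comp}"] = df[f"daily_{comp}"] * days
    per_animal = np.maximum(
        0.0, df[["mer_m", "mer_g", "mer_l", "mer_t"]].sum(axis=1) - df["credit"]
    )
    df["mer_total"] = per_animal
    df["category_headcount"] = df["headcount"] * df["share"]
    df["total_mj"] = df["category_headcount"] * per_animal

    demand = df.groupby(["cell_id", "year"], as_index=False)["total_mj"].sum().rename(columns={"total_mj": "d_mj"})
    tlu = compute_tlu(livestock, herd)
    demand = demand.merge(tlu, on=["cell_id", "year"])
    demand["mer_per_tlu"] = np.where(demand["tlu"] > 0, demand["d_mj"] / demand["tlu"].replace(0, np.nan), np.nan)

    breakdown = None
    if with_breakdown:
        breakdown = df[
            ["cell_id", "year", "species", "category", "season", "category_headcount",
             "mer_m", "mer_g", "mer_l", "mer_t", "credit", "mer_total", "total_mj"]
        ].rename(columns={"credit": "mobilization_credit"}).sort_values(
            ["cell_id", "year", "species", "category", "season"], ignore_index=True
        )
    return demand.sort_values(["cell_id", "year"], ignore_index=True), breakdown
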