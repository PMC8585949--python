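"""Metabolizable-energy supply from dry-matter production.

Usable energy per hectare is dry matter times the proper-use fraction (the
share that can be taken without degrading the resource) times the ME content
of the feed, with two corrections: pasture productivity is raised by a grazing
uplift (optimally managed rotational grazing), and crop residues lose nutritive
value in storage at a compound monthly decay rate after harvest.  Browse enters
as digestible dry matter and only carries its 0.38 availability factor
(take-70%/leave-30% of foliage times the 55% usability of what is taken).
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .biomass import DAYS_PER_MONTH

RESIDUE_CLASSES = ("residue_maize", "residue_millet", "residue_sorghum", "residue_groundnut")


def browse_availability(take_fraction: float = 0.70, usable_fraction: float = 0.55) -> float:
    """Fraction of browse foliage available to livestock (0.70 * 0.55 = 0.385)."""
    return take_fraction * usable_fraction


@dataclass
class FeedParams:
    """Proper-use and ME parameters per (feed_class, part, zone)."""

    table: pd.DataFrame
    grazing_uplift: float = 0.076
    decay_per_month: float = 0.08

    @classmethod
    def default(cls) -> "FeedParams":
        """The shipped parameter file (Table-1 values)."""
        with resources.files("sahelcc.data").joinpath("feed_params.yaml").open("r") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def from_yaml(cls, path: str) -> "FeedParams":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def from_dict(cls, raw: dict) -> "FeedParams":
        table = pd.DataFrame(raw["feeds"])
        bad = table[(table["me_min"] > table["me_avg"]) | (table["me_avg"] > table["me_max"])]
        if len(bad):
            raise ValueError(f"me_min <= me_avg <= me_max violated for {bad['feed_class'].tolist()}")
        if ((table["proper_use"] < 0) | (table["proper_use"] > 1)).any():
            raise ValueError("proper_use fractions must lie in [0, 1]")
        return cls(
            table=table,
            grazing_uplift=float(raw.get("grazing_uplift", 0.076)),
            decay_per_month=float(raw.get("decay_per_month", 0.08)),
        )

    def lookup(self, feed_class: str, part: str, zone: str) -> pd.Series:
        t = self.table
        hit = t[(t.feed_class == feed_class) & (t.part == part) & (t.zone.isin([zone, "any"]))]
        if len(hit) == 0:
            raise KeyError(f"no feed parameters for ({feed_class!r}, {part!r}, {zone!r})")
        return hit.iloc[0]


def residue_decay_factor(months_stored: float, decay_per_month: float = 0.08) -> float:
    """Remaining nutritive-value fraction after storage: (1 - d)^months."""
    if not 0.0 <= decay_per_month < 1.0:
        raise ValueError(f"decay_per_month must lie in [0, 1), got {decay_per_month}")
    months = np.asarray(months_stored, dtype=float)
    if np.any(months < 0):
        raise ValueError("months_stored must be >= 0")
    out = (1.0 - decay_per_month) ** months
    return float(out) if out.ndim == 0 else out


def usable_energy(
    dm_kg_ha,
    feed_class: str,
    part: str,
    zone: str,
    months_stored: float = 0.0,
    params: FeedParams | None = None,
    me: str = "avg",
) -> float:
    """MJ ME per hectare usable from ``dm_kg_ha`` of one feed.

    dm * proper_use * me; forage additionally * (1 + grazing uplift); residues
    additionally * compound storage decay.  ``me`` selects the avg (default),
    min or max ME column for uncertainty bands.
    """
    params = params or FeedParams.default()
    row = params.lookup(feed_class, part, zone)
    energy = np.asarray(dm_kg_ha, dtype=float) * row["proper_use"] * row[f"me_{me}"]
    if feed_class == "forage":
        energy = energy * (1.0 + params.grazing_uplift)
    if feed_class in RESIDUE_CLASSES:
        energy = energy * residue_decay_factor(months_stored, params.decay_per_month)
    return float(energy) if energy.ndim == 0 else energy


def cell_supply(
    biomass: pd.DataFrame,
    cells: pd.DataFrame,
    seasons: pd.DataFrame,
    params: FeedParams | None = None,
    wet_forage_share: float = 0.8,
    me: str = "avg",
) -> pd.DataFrame:
    """Seasonal ME supply per cell-year and feed class (MJ per cell).

    Forage splits between wet and dry season by ``wet_forage_share`` (standing
    hay carries the rest into the dry season); browse splits in proportion to
    season day counts; residues are dry-season feed with storage decay applied
    at the dry-season midpoint.  Rows for wet, dry and their annual sum are all
    emitted; annual = wet + dry by construction.
    """
    params = params or FeedParams.default()
    known = set(cells["cell_id"])
    orphans = sorted(set(biomass["cell_id"]) - known)
    if orphans:
        raise ValueError(f"biomass rows reference unknown cell_ids: {orphans[:10]}")

    df = biomass.merge(cells[["cell_id", "zone", "area_ha"]], on="cell_id", validate="many_to_one")
    df = df.merge(seasons[["cell_id", "year", "wet_days", "dry_days"]], on=["cell_id", "year"], how="left")
    if df["wet_days"].isna().any():
        missing = df.loc[df["wet_days"].isna(), ["cell_id", "year"]].drop_duplicates()
        raise ValueError(f"missing season mask for cell-years like {missing.head().to_records(index=False).tolist()}")

    pt = params.table
    key = df["feed_class"] + "|" + df["part"] + "|" + df["zone"]
    param_rows = pt.assign(
        k1=pt.feed_class + "|" + pt.part + "|" + pt.zone,
    ).set_index("k1")
    any_rows = pt[pt.zone == "any"].assign(k2=lambda t: t.feed_class + "|" + t.part).set_index("k2")

    pu = key.map(param_rows["proper_use"])
    mecol = key.map(param_rows[f"me_{me}"])
    fallback = df["feed_class"] + "|" + df["part"]
    pu = pu.fillna(fallback.map(any_rows["proper_use"]))
    mecol = mecol.fillna(fallback.map(any_rows[f"me_{me}"]))
    if pu.isna().any():
        bad = df.loc[pu.isna(), ["feed_class", "part", "zone"]].drop_duplicates()
        raise KeyError(f"no feed parameters for {bad.to_records(index=False).tolist()}")

    energy = df["dm_kg_ha"].to_numpy() * pu.to_numpy() * mecol.to_numpy() * df["area_ha"].to_numpy()
    is_forage = (df["feed_class"] == "forage").to_numpy()
    is_browse = (df["feed_class"] == "browse").to_numpy()
    is_residue = df["feed_class"].isin(RESIDUE_CLASSES).to_numpy()
    energy = np.where(is_forage, energy * (1.0 + params.grazing_uplift), energy)
    months_stored = df["dry_days"].to_numpy() / DAYS_PER_MONTH / 2.0
    energy = np.where(
        is_residue, energy * (1.0 - params.decay_per_month) ** months_stored, energy
    )

    wet_days = df["wet_days"].to_numpy()
    dry_days = df["dry_days"].to_numpy()
    day_frac_wet = np.divide(wet_days, wet_days + dry_days, out=np.zeros_like(energy), where=(wet_days + dry_days) > 0)
    wet_share = np.where(
        is_forage,
        np.where(wet_days > 0, wet_forage_share, 0.0),
        np.where(is_browse, day_frac_wet, 0.0),  # residues: dry season only
    )

    out = df[["cell_id", "year", "feed_class"]].copy()
    out["wet"] = energy * wet_share
    out["dry"] = energy * (1.0 - wet_share)
    grouped = out.groupby(["cell_id", "year", "feed_class"], as_index=False)[["wet", "dry"]].sum()
    long = grouped.melt(
        id_vars=["cell_id", "year", "feed_class"],
        value_vars=["wet", "dry"],
        var_name="season",
        value_name="me_supply_mj",
    )
    annual = grouped.assign(season="annual", me_supply_mj=grouped["wet"] + grouped["dry"])
    long = pd.concat([long, annual[["cell_id", "year", "feed_class", "season", "me_supply_mj"]]], ignore_index=True)
    return long.sort_values(["cell_id", "year", "feed_class", "season"], ignore_index=True)


def total_supply(supply: pd.DataFrame) -> pd.DataFrame:
    """Annual total S per cell-year (MJ), summed over feed classes."""
    s = supply[supply["season"] == "annual"].groupby(["cell_id", "year"], as_index=False)["me_supply_mj"].sum()
    return s.rename(columns={"me_supply_mj": "s_mj"})
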