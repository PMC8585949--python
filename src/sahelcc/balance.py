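"""Supply/demand balance, livestock carrying capacity, regional aggregates.

The S/D ratio of a cell-year says whether local feed energy covers the local
herd's requirement (S/D < 1 is a deficit); the livestock carrying capacity
(LCC) converts supply into the maximum sustainable stocking rate by dividing
by the energy requirement of one Tropical Livestock Unit.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_MER_PER_TLU = 9400.0  # MJ TLU-1 yr-1 fallback when a cell has no stock anywhere

DECADES = ((1981, 1990), (1991, 2000), (2001, 2010), (2011, 2020))


def cell_balance(supply_totals: pd.DataFrame, demand: pd.DataFrame, cells: pd.DataFrame) -> pd.DataFrame:
    """Per cell-year S, D, S/D, LCC and deficit flag.

    ``sd_ratio`` is +inf when D = 0 with S > 0 and NaN (excluded from
    aggregates) when both are 0.  LCC uses the cell-year demand per TLU, the
    zone-year mean where the cell has no stock, and a fixed fallback if a whole
    zone-year has none.
    """
    sup = supply_totals.rename(columns={"me_supply_mj": "s_mj"})
    only_s = set(map(tuple, sup[["cell_id", "year"]].itertuples(index=False))) ^ set(
        map(tuple, demand[["cell_id", "year"]].itertuples(index=False))
    )
    if only_s:
        raise ValueError(f"supply and demand keys mismatch, offenders include {sorted(only_s)[:10]}")
    df = sup.merge(demand, on=["cell_id", "year"], validate="one_to_one")
    df = df.merge(cells[["cell_id", "zone", "area_ha"]], on="cell_id", validate="many_to_one")

    s = df["s_mj"].to_numpy()
    d = df["d_mj"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d > 0, s / np.where(d > 0, d, 1.0), np.where(s > 0, np.inf, np.nan))
    df["sd_ratio"] = ratio
    df["deficit"] = ratio < 1.0

    zone_mer = (
        df[df["tlu"] > 0].groupby(["zone", "year"])["mer_per_tlu"].mean().rename("zone_mer")
    )
    df = df.merge(zone_mer, left_on=["zone", "year"], right_index=True, how="left")
    mer = df["mer_per_tlu"].fillna(df["zone_mer"]).fillna(DEFAULT_MER_PER_TLU)
    df["lcc_tlu_ha"] = lcc(df["s_mj"].to_numpy(), mer.to_numpy(), df["area_ha"].to_numpy())
    return df.drop(columns="zone_mer").sort_values(["cell_id", "year"], ignore_index=True)


def lcc(supply_mj, mer_per_tlu, area_ha):
    """Carrying capacity, TLU ha-1: supply / (MER per TLU) / area."""
    mer = np.asarray(mer_per_tlu, dtype=float)
    area = np.asarray(area_ha, dtype=float)
    if np.any(mer <= 0) or np.any(area <= 0):
        raise ValueError("mer_per_tlu and area_ha must be positive")
    out = np.asarray(supply_mj, dtype=float) / mer / area
    return float(out) if out.ndim == 0 else out


def regional_sd(balance: pd.DataFrame) -> pd.DataFrame:
    """Yearly regional S/D by both aggregations.

    ``ratio_of_totals`` divides summed supply by summed demand;
    ``mean_of_ratios`` is the area-weighted mean of finite cell ratios.
    """
    valid = balance[~balance["sd_ratio"].isna()]
    if valid.empty:
        raise ValueError("no valid cells to aggregate")

    def per_year(g: pd.DataFrame) -> pd.Series:
        finite = g[np.isfinite(g["sd_ratio"])]
        mean_ratio = (
            np.average(finite["sd_ratio"], weights=finite["area_ha"]) if len(finite) else np.nan
        )
        d = g["d_mj"].sum()
        return pd.Series(
            {
                "s_total_mj": g["s_mj"].sum(),
                "d_total_mj": d,
                "ratio_of_totals": g["s_mj"].sum() / d if d > 0 else np.inf,
                "mean_of_ratios": mean_ratio,
            }
        )

    out = valid.groupby("year").apply(per_year, include_groups=False).reset_index()
    return out


def deficit_area_fraction(balance: pd.DataFrame, period_years) -> float:
    """Percent of area whose period-mean S/D is below 1."""
    period = balance[balance["year"].isin(list(period_years))]
    if period.empty:
        raise ValueError("no balance rows in the requested period")
    finite = period[np.isfinite(period["sd_ratio"])]
    per_cell = finite.groupby("cell_id").agg(sd=("sd_ratio", "mean"), area=("area_ha", "first"))
    if per_cell.empty:
        return 0.0
    total_area = balance.groupby("cell_id")["area_ha"].first().sum()
    deficit_area = per_cell.loc[per_cell["sd"] < 1.0, "area"].sum()
    return float(100.0 * deficit_area / total_area)


def decadal_summary(balance: pd.DataFrame, decades=DECADES) -> pd.DataFrame:
    """Mean S, mean D, regional S/D and deficit-area percent per decade."""
    import warnings

    rows = []
    years_present = set(balance["year"])
    for y0, y1 in decades:
        span = [y for y in range(y0, y1 + 1) if y in years_present]
        if not span:
            continue
        if len(span) < y1 - y0 + 1:
            warnings.warn(f"decade {y0}-{y1} only partially covered ({len(span)} years)", stacklevel=2)
        sub = balance[balance["year"].isin(span)]
        d = sub["d_mj"].sum()
        rows.append(
            {
                "decade": f"{y0}-{y1}",
                "mean_s_mj": sub.groupby("year")["s_mj"].sum().mean(),
                "mean_d_mj": sub.groupby("year")["d_mj"].sum().mean(),
                "regional_sd": sub["s_mj"].sum() / d if d > 0 else np.inf,
                "deficit_area_pct": deficit_area_fraction(balance, span),
            }
        )
    return pd.DataFrame(rows)
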