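"""Bioclimatic indices, Mann-Kendall trend test, Sen slope, LCC association.

The three indices summarize a cell-year's climate: temperature seasonality
(population SD of the 12 monthly means x 100), precipitation seasonality (a
damped coefficient of variation of monthly totals) and the De Martonne aridity
index (mean monthly precipitation over mean temperature + 10; lower is drier).
Trends are tested with the rank-based Mann-Kendall statistic (tie-corrected
variance, continuity-corrected normal approximation) and quantified with the
Theil-Sen median pairwise slope, reported as percent of the series mean per
decade.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


def temperature_seasonality(monthly_t) -> float:
    """Population SD of the 12 monthly temperature means, times 100."""
    t = np.asarray(monthly_t, dtype=float)
    if t.shape[-1] != 12:
        raise ValueError("temperature_seasonality expects 12 monthly values")
    return np.std(t, axis=-1) * 100.0


def precipitation_seasonality(monthly_p, literal_sum: bool = False) -> float:
    """Damped CV of monthly precipitation, x100.

    Default divides the population SD by ``1 + mean(monthly)``; with
    ``literal_sum`` the divisor is ``1 + sum(monthly)`` instead.
    """
    p = np.asarray(monthly_p, dtype=float)
    if p.shape[-1] != 12:
        raise ValueError("precipitation_seasonality expects 12 monthly values")
    if np.any(p < 0):
        raise ValueError("monthly precipitation must be >= 0")
    denom = 1.0 + (p.sum(axis=-1) if literal_sum else p.mean(axis=-1))
    return np.std(p, axis=-1) / denom * 100.0


def de_martonne(monthly_p, monthly_t) -> float:
    """De Martonne aridity index: mean monthly precipitation / (mean T + 10)."""
    p = np.asarray(monthly_p, dtype=float)
    t = np.asarray(monthly_t, dtype=float)
    if p.shape[-1] != 12 or t.shape[-1] != 12:
        raise ValueError("de_martonne expects 12 monthly values of each variable")
    denom = t.mean(axis=-1) + 10.0
    if np.any(denom <= 0):
        raise ValueError("mean temperature must exceed -10 degC")
    return p.mean(axis=-1) / denom


def bioclim_table(climate: pd.DataFrame) -> pd.DataFrame:
    """The three indices per cell-year."""
    cl = climate.sort_values(["cell_id", "year", "month"])
    p = cl["precip_mm"].to_numpy().reshape(-1, 12)
    t = cl["tmean_c"].to_numpy().reshape(-1, 12)
    keys = cl[["cell_id", "year"]].iloc[::12].reset_index(drop=True)
    out = keys.copy()
    out["temp_seasonality"] = temperature_seasonality(t)
    out["precip_seasonality"] = precipitation_seasonality(p)
    out["aridity"] = de_martonne(p, t)
    return out


@dataclass
class TrendResult:
    """Mann-Kendall test plus Sen-slope magnitude for one series."""

    series_id: str
    n: int
    mk_s: int
    var_s: float
    z: float
    p_value: float
    significant_at_0_05: bool
    sen_slope: float
    pct_per_decade: float


def _mk_s_and_var(x: np.ndarray) -> tuple[int, float]:
    n = len(x)
    diff = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(diff, 1).sum())
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    return s, float(var)


def mann_kendall(series, alpha: float = 0.05, series_id: str = "series") -> TrendResult:
    """Rank-based test for a monotonic trend.

    S sums the signs of all pairwise forward differences; the variance carries
    the standard tie correction; Z uses a +/-1 continuity correction and the
    two-sided normal p-value.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 3:
        raise ValueError("mann_kendall needs at least 3 observations")
    s, var = _mk_s_and_var(x)
    if var > 0 and s != 0:
        z = (s - np.sign(s)) / np.sqrt(var)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    slope = sen_slope(x)
    return TrendResult(
        series_id=series_id,
        n=len(x),
        mk_s=s,
        var_s=var,
        z=float(z),
        p_value=float(p),
        significant_at_0_05=bool(p < alpha),
        sen_slope=float(slope),
        pct_per_decade=float(pct_per_decade(x)),
    )


def sen_slope(series) -> float:
    """Theil-Sen estimator: median of all pairwise slopes per time step."""
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("sen_slope needs at least 2 observations")
    i, j = np.triu_indices(n, 1)
    return float(np.median((x[j] - x[i]) / (j - i)))


def pct_per_decade(series) -> float:
    """Sen slope normalized by the series mean, in percent per decade."""
    x = np.asarray(series, dtype=float)
    mean = x.mean()
    if mean == 0:
        return float("nan")
    return 10.0 * sen_slope(x) / mean * 100.0


def trend_table(series_map: dict[str, "pd.Series | np.ndarray"], alpha: float = 0.05) -> pd.DataFrame:
    """Mann-Kendall + Sen results for a set of named yearly series."""
    rows = []
    for name, values in series_map.items():
        r = mann_kendall(np.asarray(values, dtype=float), alpha=alpha, series_id=name)
        rows.append(vars(r))
    return pd.DataFrame(rows)


def lcc_bioclim_association(lcc_by_cell, bioclim_by_cell: pd.DataFrame) -> dict:
    """Pearson r and power-law fit LCC = a * x^b per bioclimatic index.

    Expects one row per cell in both inputs (period means).  Degenerate
    (constant) indices or LCC yield NaN correlations and no fit.
    """
    lcc = np.asarray(lcc_by_cell, dtype=float)
    if len(lcc) < 3:
        raise ValueError("need at least 3 cells")
    out = {}
    for col in ("temp_seasonality", "precip_seasonality", "aridity"):
        x = bioclim_by_cell[col].to_numpy(dtype=float)
        res: dict = {"r": np.nan, "a": np.nan, "b": np.nan}
        if np.std(x) > 0 and np.std(lcc) > 0:
            res["r"] = float(stats.pearsonr(x, lcc)[0])
            pos = (x > 0) & (lcc > 0)
            if pos.sum() >= 3 and np.std(np.log(x[pos])) > 0:
                # least-squares in log space, a robust seed for the power law
                b, loga = np.polyfit(np.log(x[pos]), np.log(lcc[pos]), 1)
                try:
                    (a_fit, b_fit), _ = optimize.curve_fit(
                        lambda xx, a, b: a * xx**b, x[pos], lcc[pos],
                        p0=(np.exp(loga), b), maxfev=5000,
                    )
                    res["a"], res["b"] = float(a_fit), float(b_fit)
                except RuntimeError:
                    res["a"], res["b"] = float(np.exp(loga)), float(b)
        out[col] = res
    return out
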