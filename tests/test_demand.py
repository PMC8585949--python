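"""Herd splitting, MER component forms, TLU and per-cell demand."""
import numpy as np
import pandas as pd
import pytest

from sahelcc.biomass import classify_seasons
from sahelcc.calibrate import archetype_cells, _archetype_climate
from sahelcc.config import SAHELIAN, SUDANIAN, DomainConfig
from sahelcc.demand import (
    HerdParams,
    cell_demand,
    compute_tlu,
    mer_growth,
    mer_lactation,
    mer_maintenance,
    mer_travel,
    seasonal_category_demand,
    split_herd,
)
from sahelcc.synthgrid import build_domain, generate_climate, generate_livestock


class TestMerComponents:
    def test_maintenance_reference_evaluation(self):
        # 1.2 * 0.26 * 250^0.75 * exp(-0.12) / (0.02*6.5 + 0.5)
        val = mer_maintenance(250, 4, sex_multiplier=1.0, species_factor=1.2, diet_me_mj_kg=6.5)
        assert val == pytest.approx(1.2 * 0.26 * 250**0.75 * np.exp(-0.12) / 0.63, rel=1e-12)
        assert val == pytest.approx(27.62, abs=0.02)

    def test_maintenance_age_zero_and_scaling(self):
        base = mer_maintenance(300, 0, species_factor=1.2, diet_me_mj_kg=6.5)
        assert base == pytest.approx(1.2 * 0.26 * 300**0.75 / 0.63, rel=1e-12)
        assert mer_maintenance(300, 0, species_factor=2.4, diet_me_mj_kg=6.5) == pytest.approx(2 * base)

    def test_maintenance_rejects_nonpositive_weight(self):
        with pytest.raises(ValueError):
            mer_maintenance(0, 3)

    def test_growth_reference_evaluation(self):
        assert mer_growth(0.2, 17.0, 6.5) == pytest.approx(0.2 * 17 / 0.279, rel=1e-12)
        assert mer_growth(0.2, 17.0, 6.5) == pytest.approx(12.19, abs=0.01)
        assert mer_growth(0.0) == 0.0
        assert mer_growth(0.1, 17.0, 6.5) == pytest.approx(mer_growth(0.2, 17.0, 6.5) / 2)

    def test_lactation_reference_evaluation(self):
        assert mer_lactation(1.5) == pytest.approx(7.75)
        assert mer_lactation(3.0) == pytest.approx(15.5)
        assert mer_lactation(0.0) == 0.0
        with pytest.raises(ValueError):
            mer_lactation(1.0, k_l=0.0)

    def test_travel_reference_evaluation(self):
        assert mer_travel(250, 10, 2.6, 6.5) == pytest.approx(0.0026 * 250 * 10 / 0.63, rel=1e-12)
        assert mer_travel(250, 10, 2.6, 6.5) == pytest.approx(10.32, abs=0.005)
        assert mer_travel(250, 0) == 0.0
        assert mer_travel(250, 5, 2.6, 6.5) == pytest.approx(mer_travel(250, 10, 2.6, 6.5) / 2)


class TestSeasonalCategoryDemand:
    def test_wet_season_has_no_mobilization(self):
        herd = HerdParams.default()
        r = seasonal_category_demand(herd, "cattle", "cow", "wet", 183, SUDANIAN)
        assert r["mobilization_credit"] == 0.0
        assert r["mer_total"] == pytest.approx(sum(r[f"mer_{c}"] for c in "mglt"))

    def test_cow_dry_season_mobilization_credit(self):
        herd = HerdParams.default()
        r = seasonal_category_demand(herd, "cattle", "cow", "dry", 182, SUDANIAN)
        assert r["mobilization_credit"] == pytest.approx(250 * 0.12 * 28 * 0.84)  # 705.6 MJ

    def test_immature_small_ruminant_dry_gain_reduction(self):
        herd = HerdParams.default()
        wet = seasonal_category_demand(herd, "goat", "young", "wet", 100, SUDANIAN)
        dry = seasonal_category_demand(herd, "goat", "young", "dry", 100, SUDANIAN)
        assert dry["mer_g"] / wet["mer_g"] == pytest.approx(0.7, rel=1e-9)

    def test_total_floored_at_zero(self):
        herd = HerdParams.default()
        r = seasonal_category_demand(herd, "cattle", "cow", "dry", 1, SUDANIAN)
        assert r["mer_total"] == 0.0  # one dry day cannot outweigh the seasonal credit

    def test_unknown_season_rejected(self):
        with pytest.raises(ValueError, match="season"):
            seasonal_category_demand(HerdParams.default(), "cattle", "cow", "monsoon", 100, SUDANIAN)


class TestHerdAndTlu:
    def test_split_conserves_headcount(self):
        herd = HerdParams.default()
        stock = pd.DataFrame(
            {"cell_id": [0, 0, 1], "year": 2000, "species": ["cattle", "sheep", "goat"], "headcount": [100.0, 55.5, 0.0]}
        )
        split = split_herd(stock, herd)
        sums = split.groupby(["cell_id", "species"])["headcount"].sum()
        assert sums.loc[(0, "cattle")] == pytest.approx(100.0, abs=1e-9)
        assert sums.loc[(0, "sheep")] == pytest.approx(55.5, abs=1e-9)
        assert sums.loc[(1, "goat")] == 0.0
        cows = split[(split.species == "cattle") & (split.category == "cow")]["headcount"].iloc[0]
        assert cows == pytest.approx(45.0)

    def test_split_unknown_species(self):
        stock = pd.DataFrame({"cell_id": [0], "year": 2000, "species": ["camel"], "headcount": [1.0]})
        with pytest.raises(KeyError, match="camel"):
            split_herd(stock, HerdParams.default())

    def test_tlu_formula_hand_example(self):
        herd = HerdParams.from_dict(
            {
                "species": {
                    "cattle": {
                        "species_factor": 1.2,
                        "dry_weight_loss": "cattle",
                        "categories": [
                            {"name": "big", "share": 0.4, "mlw_kg": 300, "age_yr": 3, "adg_wet": 0, "adg_dry": 0,
                             "milk_wet": 0, "milk_dry": 0, "dist_wet_km": 0, "dist_dry_km": 0, "sex_multiplier": 1},
                            {"name": "small", "share": 0.6, "mlw_kg": 125, "age_yr": 1, "adg_wet": 0, "adg_dry": 0,
                             "milk_wet": 0, "milk_dry": 0, "dist_wet_km": 0, "dist_dry_km": 0, "sex_multiplier": 1},
                        ],
                    }
                },
                "energy": HerdParams.default().energy,
                "diet_me_mj_kg": {"sahelian": 6.1, "sudanian": 6.5},
            }
        )
        stock = pd.DataFrame({"cell_id": [0], "year": [2000], "species": ["cattle"], "headcount": [1000.0]})
        tlu = compute_tlu(stock, herd)
        assert tlu["tlu"].iloc[0] == pytest.approx((1.2 * 0.4 + 0.5 * 0.6) * 1000)  # 780

    def test_identity_weight_tlu(self):
        herd = HerdParams.default()
        assert herd.tlu_per_head("cattle") == pytest.approx(
            sum(c["share"] * c["mlw_kg"] for c in herd.species["cattle"]["categories"]) / 250.0
        )


class TestCellDemand:
    def _inputs(self, n_cells=30, seed=21, years=(2000, 2001)):
        cfg = DomainConfig(n_cells=n_cells, seed=seed, climate_noise=False)
        cells = build_domain(cfg)
        climate = generate_climate(cells, range(years[0], years[1] + 1), cfg)
        seasons = classify_seasons(climate)
        stock = generate_livestock(cells, range(years[0], years[1] + 1), cfg)
        return cells, seasons, stock

    def test_zero_livestock_zero_demand(self):
        cells, seasons, stock = self._inputs()
        demand, _ = cell_demand(stock.assign(headcount=0.0), HerdParams.default(), seasons, cells)
        assert (demand["d_mj"] == 0).all()
        assert demand["mer_per_tlu"].isna().all()

    def test_single_cow_matches_seasonal_sum(self):
        herd = HerdParams.default()
        cells = archetype_cells().iloc[[1]].reset_index(drop=True)
        climate = _archetype_climate(cells, {SUDANIAN: 670.0})
        seasons = classify_seasons(climate)
        wet_days = int(seasons["wet_days"].iloc[0])
        one_cow = HerdParams.from_dict(
            {
                "species": {
                    "cattle": {
                        "species_factor": herd.species["cattle"]["species_factor"],
                        "dry_weight_loss": "cattle",
                        "categories": [
                            {**next(c for c in herd.species["cattle"]["categories"] if c["name"] == "cow"),
                             "share": 1.0}
                        ],
                    }
                },
                "energy": herd.energy,
                "diet_me_mj_kg": herd.diet_me_mj_kg,
            }
        )
        stock = pd.DataFrame({"cell_id": [1], "year": [2000], "species": ["cattle"], "headcount": [1.0]})
        demand, breakdown = cell_demand(stock, one_cow, seasons, cells)
        expected = (
            seasonal_category_demand(one_cow, "cattle", "cow", "wet", wet_days, SUDANIAN)["mer_total"]
            + seasonal_category_demand(one_cow, "cattle", "cow", "dry", 365 - wet_days, SUDANIAN)["mer_total"]
        )
        assert demand["d_mj"].iloc[0] == pytest.approx(expected, rel=1e-12)
        assert breakdown["total_mj"].sum() == pytest.approx(expected, rel=1e-12)

    def test_demand_monotone_in_headcount(self):
        cells, seasons, stock = self._inputs()
        herd = HerdParams.default()
        d1, _ = cell_demand(stock, herd, seasons, cells, with_breakdown=False)
        d2, _ = cell_demand(stock.assign(headcount=stock["headcount"] * 1.5), herd, seasons, cells, with_breakdown=False)
        assert (d2["d_mj"] > d1["d_mj"]).all()
        assert np.allclose(d2["d_mj"], 1.5 * d1["d_mj"], rtol=1e-9)

    def test_missing_season_mask_rejected(self):
        cells, seasons, stock = self._inputs()
        with pytest.raises(ValueError, match="season mask"):
            cell_demand(stock, HerdParams.default(), seasons[seasons.year != 2001], cells)

    def test_components_non_negative(self):
        cells, seasons, stock = self._inputs()
        _, breakdown = cell_demand(stock, HerdParams.default(), seasons, cells)
        for col in ("mer_m", "mer_g", "mer_l", "mer_t", "mer_total", "mobilization_credit"):
            assert (breakdown[col] >= 0).all()
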