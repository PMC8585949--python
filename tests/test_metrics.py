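"""Bioclimatic indices and trend statistics against independent oracles."""
import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sahelcc.metrics import (
    de_martonne,
    lcc_bioclim_association,
    mann_kendall,
    pct_per_decade,
    precipitation_seasonality,
    sen_slope,
    temperature_seasonality,
)


def brute_force_mk(x):
    """O(n^2) oracle: S, tie-corrected variance, continuity-corrected p."""
    n = len(x)
    s = 0
    for i in range(n):
        for j in range(i + 1, n):
            s += int(x[j] > x[i]) - int(x[j] < x[i])
    ties = [c for c in Counter(x).values() if c > 1]
    var = (n * (n - 1) * (2 * n + 5) - sum(t * (t - 1) * (2 * t + 5) for t in ties)) / 18
    if s == 0 or var == 0:
        z = 0.0
    else:
        z = (s - math.copysign(1, s)) / math.sqrt(var)
    return s, var, 2 * stats.norm.sf(abs(z))


class TestIndices:
    def test_temperature_seasonality(self):
        assert temperature_seasonality([25.0] * 12) == 0.0
        assert temperature_seasonality([20.0, 30.0] * 6) == pytest.approx(500.0)
        shifted = temperature_seasonality(np.array([20.0, 30.0] * 6) + 7.3)
        assert shifted == pytest.approx(500.0)

    def test_precipitation_seasonality(self):
        assert precipitation_seasonality([40.0] * 12) == 0.0
        spike = [120.0] + [0.0] * 11
        sd = math.sqrt((110**2 + 11 * 10**2) / 12)
        assert precipitation_seasonality(spike) == pytest.approx(sd / 11 * 100, rel=1e-9)
        assert precipitation_seasonality(spike) == pytest.approx(301.51, abs=0.01)
        # large totals converge to a plain CV
        big = np.array(spike) * 1e6
        cv = np.std(big) / np.mean(big) * 100
        assert precipitation_seasonality(big) == pytest.approx(cv, rel=1e-4)
        with pytest.raises(ValueError):
            precipitation_seasonality([-1.0] + [0.0] * 11)

    def test_precipitation_seasonality_literal_sum_variant(self):
        spike = [120.0] + [0.0] * 11
        sd = math.sqrt((110**2 + 11 * 10**2) / 12)
        assert precipitation_seasonality(spike, literal_sum=True) == pytest.approx(sd / 121 * 100)

    def test_de_martonne(self):
        months = np.full(12, 245.0 / 12)
        temps = np.full(12, 29.0)
        assert de_martonne(months, temps) == pytest.approx((245 / 12) / 39, abs=1e-9)
        assert de_martonne(months, temps) == pytest.approx(0.5235, abs=1e-4)
        assert de_martonne(np.zeros(12), temps) == 0.0
        assert de_martonne(2 * months, temps) == pytest.approx(2 * de_martonne(months, temps))
        with pytest.raises(ValueError):
            de_martonne(months, np.full(12, -15.0))


class TestMannKendall:
    @pytest.mark.parametrize(
        "series,expected_s",
        [([1, 2, 3, 4, 5], 10), ([3, 1, 2], -1), ([2, 2, 2, 2], 0)],
    )
    def test_statistic_hand_examples(self, series, expected_s):
        assert mann_kendall(series).mk_s == expected_s

    def test_constant_series_not_significant(self):
        r = mann_kendall([5.0] * 10)
        assert r.mk_s == 0 and r.p_value == 1.0 and not r.significant_at_0_05

    def test_minimum_length(self):
        with pytest.raises(ValueError):
            mann_kendall([1, 2])

    def test_brute_force_oracle_on_random_series(self):
        """S exact and p within 1e-12 of the closed form, on 200 seeded series."""
        rng = np.random.default_rng(20240917)
        for _ in range(200):
            n = int(rng.integers(5, 51))
            if rng.random() < 0.5:  # force ties by discretizing
                x = rng.integers(0, 5, size=n).astype(float)
            else:
                x = rng.normal(size=n)
            s, var, p = brute_force_mk(list(x))
            r = mann_kendall(x)
            assert r.mk_s == s
            assert r.var_s == pytest.approx(var, rel=1e-12)
            assert r.p_value == pytest.approx(p, abs=1e-12)

    def test_reversal_negates_s_preserves_p(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=25)
        fwd, rev = mann_kendall(x), mann_kendall(x[::-1])
        assert rev.mk_s == -fwd.mk_s
        assert rev.p_value == pytest.approx(fwd.p_value, abs=1e-15)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=30))
    def test_s_bound_property(self, xs):
        r = mann_kendall(xs)
        n = len(xs)
        assert abs(r.mk_s) <= n * (n - 1) // 2
        assert 0.0 <= r.p_value <= 1.0


class TestSenSlope:
    def test_exact_line(self):
        assert sen_slope([1.0, 3.0, 5.0, 7.0]) == pytest.approx(2.0)
        assert sen_slope([4.0, 4.0, 4.0]) == 0.0

    def test_pairwise_median_example(self):
        assert sen_slope([0.0, 10.0, 5.0]) == pytest.approx(2.5)  # slopes {10, -5, 2.5}

    def test_minimum_length(self):
        with pytest.raises(ValueError):
            sen_slope([1.0])

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-100, 100), st.floats(-10, 10), st.integers(5, 40))
    def test_recovers_linear_trend(self, intercept, slope, n):
        series = intercept + slope * np.arange(n)
        assert sen_slope(series) == pytest.approx(slope, abs=1e-9)


class TestPctPerDecade:
    def test_hand_example(self):
        assert pct_per_decade([10.0, 20.0, 30.0, 40.0]) == pytest.approx(400.0)

    def test_constant_and_sign(self):
        assert pct_per_decade([7.0] * 8) == 0.0
        assert pct_per_decade([30.0, 20.0, 10.0]) < 0
        assert math.isnan(pct_per_decade([-1.0, 0.0, 1.0]))


class TestLccBioclimAssociation:
    def _bioclim(self, aridity, n):
        rng = np.random.default_rng(12)
        return pd.DataFrame(
            {
                "temp_seasonality": rng.uniform(100, 300, n),
                "precip_seasonality": rng.uniform(50, 350, n),
                "aridity": aridity,
            }
        )

    def test_perfect_linear_relation(self):
        aridity = np.linspace(0.2, 2.0, 50)
        out = lcc_bioclim_association(2.0 * aridity, self._bioclim(aridity, 50))
        assert out["aridity"]["r"] == pytest.approx(1.0)
        assert out["aridity"]["a"] == pytest.approx(2.0, rel=1e-3)
        assert out["aridity"]["b"] == pytest.approx(1.0, rel=1e-3)

    def test_independent_noise_low_correlation(self):
        rng = np.random.default_rng(99)
        n = 1000
        aridity = rng.uniform(0.2, 2.0, n)
        lcc = rng.uniform(0.0, 1.0, n)
        out = lcc_bioclim_association(lcc, self._bioclim(aridity, n))
        assert abs(out["aridity"]["r"]) < 0.15

    def test_constant_lcc_undefined(self):
        aridity = np.linspace(0.2, 2.0, 20)
        out = lcc_bioclim_association(np.full(20, 0.5), self._bioclim(aridity, 20))
        assert math.isnan(out["aridity"]["r"])

    def test_too_few_cells(self):
        with pytest.raises(ValueError):
            lcc_bioclim_association([1.0, 2.0], self._bioclim([0.5, 0.6], 2))
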