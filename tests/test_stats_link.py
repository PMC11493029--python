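"""Zonal means, Pearson correlation and the multi-scale matrix."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.special import gammaln

from mcrisk import (Raster, WaterQualityTable, monthly_mean, pearson,
                    pearson_pvalue, zonal_mean)
from mcrisk.cost_distance import MCRSurface
from mcrisk.grid_io import WQ_INDEXES
from mcrisk.spatial_scales import Zone, ZoneSet
from mcrisk.stats_link import correlation_matrix


def textbook_pearson(x, y):
    """The n·ΣXY − ΣXΣY formula, evaluated directly."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    num = n * np.sum(x * y) - np.sum(x) * np.sum(y)
    den = np.sqrt((n * np.sum(x**2) - np.sum(x) ** 2)
                  * (n * np.sum(y**2) - np.sum(y) ** 2))
    return num / den


def t_tail_oracle(t_val, df):
    """Two-sided tail of Student's t by numerical integration of the pdf."""
    def pdf(u):
        logc = gammaln((df + 1) / 2) - gammaln(df / 2) \
            - 0.5 * np.log(df * np.pi)
        return np.exp(logc - (df + 1) / 2 * np.log1p(u * u / df))
    tail, _ = quad(pdf, abs(t_val), np.inf)
    return 2 * tail


class TestMonthlyMean:
    def _samples(self, per_river):
        return {river: {idx: vals for idx in WQ_INDEXES}
                for river, vals in per_river.items()}

    def test_identical_months(self):
        wq = monthly_mean(self._samples({"A": [2.5] * 12, "B": [1.0] * 12,
                                         "C": [3.0] * 12}))
        assert wq.rows["A"]["TP"] == 2.5

    def test_partial_year(self):
        wq = monthly_mean(self._samples({"A": [1.0, 3.0], "B": [2.0],
                                         "C": [4.0] * 5}))
        assert wq.rows["A"]["TN"] == 2.0

    def test_matches_direct_mean(self):
        rng = np.random.default_rng(8)
        arr = rng.uniform(0, 10, size=(19, 7, 12))
        samples = {
            f"R{i}": {idx: list(arr[i, k]) for k, idx in enumerate(WQ_INDEXES)}
            for i in range(19)}
        wq = monthly_mean(samples)
        for i in range(19):
            for k, idx in enumerate(WQ_INDEXES):
                assert wq.rows[f"R{i}"][idx] == pytest.approx(
                    arr[i, k].mean(), abs=1e-12)

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            monthly_mean({"A": {idx: [] for idx in WQ_INDEXES}})


def _mcr(values):
    return MCRSurface(raster=Raster(values=np.asarray(values, float),
                                    cell_size=30.0, semantic="mcr"),
                      source_type="PFSL")


def _zoneset(masks, scale="subbasin"):
    return ZoneSet(scale_name=scale, zones={
        i + 1: Zone(name=f"R{i}", mask=m) for i, m in enumerate(masks)})


class TestZonalMean:
    def test_constant_zone(self):
        vals = np.full((4, 4), 7.0)
        mask = np.zeros((4, 4), bool)
        mask[:2] = True
        stats = zonal_mean(_mcr(vals), _zoneset([mask]))
        assert stats[0].mean_mcr == 7.0
        assert stats[0].n_cells == 8

    def test_two_cell_zone(self):
        vals = np.array([[2.0, 4.0], [9.0, 9.0]])
        mask = np.array([[True, True], [False, False]])
        stats = zonal_mean(_mcr(vals), _zoneset([mask]))
        assert stats[0].mean_mcr == 3.0

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(9)
        vals = rng.uniform(0, 100, size=(12, 12))
        masks = [rng.random((12, 12)) < 0.3 for _ in range(4)]
        stats = zonal_mean(_mcr(vals), _zoneset(masks))
        for zs, mask in zip(stats, masks):
            manual = np.mean([vals[i, j] for i in range(12) for j in range(12)
                              if mask[i, j]])
            assert zs.mean_mcr == pytest.approx(manual, abs=1e-12)

    def test_empty_zone_dropped(self):
        vals = np.ones((3, 3))
        stats = zonal_mean(_mcr(vals),
                           _zoneset([np.zeros((3, 3), bool),
                                     np.ones((3, 3), bool)]))
        assert len(stats) == 1
        assert stats[0].river == "R1"

    def test_infinite_cells_excluded(self):
        vals = np.array([[1.0, -9999.0], [3.0, 5.0]])
        mask = np.ones((2, 2), bool)
        stats = zonal_mean(_mcr(vals), _zoneset([mask]))
        assert stats[0].mean_mcr == 3.0
        assert stats[0].n_cells == 3


class TestPearson:
    def test_exact_linearity(self):
        assert pearson([1, 2, 3], [2, 4, 6]) == 1.0
        assert pearson([1, 2, 3], [6, 4, 2]) == -1.0

    def test_table3_column_pair_matches_textbook_formula(self, wq_table):
        x = wq_table.column("NH3-N")
        y = wq_table.column("TP")
        assert pearson(x, y) == pytest.approx(textbook_pearson(x, y),
                                              abs=1e-12)

    @pytest.mark.parametrize("a,b", [("TN", "COD_Mn"), ("BOD5", "COD_Cr"),
                                     ("Fluoride", "NH3-N")])
    def test_more_printed_column_pairs(self, wq_table, a, b):
        x, y = wq_table.column(a), wq_table.column(b)
        assert pearson(x, y) == pytest.approx(textbook_pearson(x, y),
                                              abs=1e-12)

    @given(a=st.floats(0.01, 50), b=st.floats(-100, 100))
    @settings(max_examples=30, deadline=None)
    def test_affine_invariance_and_antisymmetry(self, a, b):
        x = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        y = np.array([2.0, 1.0, 7.0, 3.0, 9.0])
        r = pearson(x, y)
        assert pearson(a * x + b, y) == pytest.approx(r, abs=1e-9)
        assert pearson(-x, y) == pytest.approx(-r, abs=1e-12)
        assert pearson(y, x) == pytest.approx(r, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [2, 3, 4])

    def test_sign_of_slope_recovered_exactly(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        assert pearson(x, 2.5 * x + 1) == 1.0
        assert pearson(x, -0.3 * x + 7) == -1.0


class TestPearsonPvalue:
    def test_r_zero_gives_one(self):
        assert pearson_pvalue(0.0, 19) == 1.0

    def test_perfect_correlation_gives_zero(self):
        assert pearson_pvalue(1.0, 5) == 0.0
        assert pearson_pvalue(-1.0, 5) == 0.0

    @pytest.mark.parametrize("r,n", [(0.5, 19), (-0.7, 10), (0.2, 30)])
    def test_matches_t_tail_integration(self, r, n):
        t = r * np.sqrt((n - 2) / (1 - r * r))
        assert pearson_pvalue(r, n) == pytest.approx(
            t_tail_oracle(t, n - 2), abs=1e-9)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            pearson_pvalue(0.5, 2)


class TestCorrelationMatrix:
    def _stats(self, means, scale="buffer_1000", stype="PFSL"):
        return [type("Z", (), dict(scale_name=scale, zone_id=i + 1,
                                   river=r, source_type=stype,
                                   mean_mcr=m, n_cells=10))()
                for i, (r, m) in enumerate(means.items())]

    def test_planted_noise_free_link_gives_minus_one(self):
        means = {f"R{i}": 100.0 * (i + 1) for i in range(5)}
        rows = {r: {idx: 50.0 - 0.01 * m for idx in WQ_INDEXES}
                for r, m in means.items()}
        wq = WaterQualityTable(rows=rows)
        out = correlation_matrix(self._stats(means), wq)
        for c in out:
            assert c.r == pytest.approx(-1.0)
            assert c.significance == "0.01"

    def test_zero_variance_zone_means_flagged(self):
        means = {f"R{i}": 42.0 for i in range(5)}
        rng = np.random.default_rng(1)
        rows = {r: {idx: float(rng.uniform(1, 5)) for idx in WQ_INDEXES}
                for r in means}
        out = correlation_matrix(self._stats(means),
                                 WaterQualityTable(rows=rows))
        assert all(c.insufficient for c in out)
        assert all(np.isnan(c.r) for c in out)

    def test_unmatched_rivers_excluded_pairwise(self):
        means = {f"R{i}": 10.0 * (i + 1) for i in range(6)}
        rows = {r: {idx: 100.0 - m for idx in WQ_INDEXES}
                for r, m in list(means.items())[:4]}
        out = correlation_matrix(self._stats(means),
                                 WaterQualityTable(rows=rows))
        assert all(c.n == 4 for c in out)

    def test_significance_stars_consistent(self):
        rng = np.random.default_rng(2)
        means = {f"R{i}": float(rng.uniform(0, 100)) for i in range(19)}
        rows = {r: {idx: float(rng.uniform(1, 5)) for idx in WQ_INDEXES}
                for r in means}
        out = correlation_matrix(self._stats(means),
                                 WaterQualityTable(rows=rows))
        for c in out:
            if c.p < 0.01:
                assert c.significance == "0.01"
            elif c.p < 0.05:
                assert c.significance == "0.05"
            else:
                assert c.significance == ""

    def test_no_matches_rejected(self):
        means = {"A": 1.0, "B": 2.0, "C": 3.0}
        rows = {"X": {idx: 1.0 for idx in WQ_INDEXES},
                "Y": {idx: 2.0 for idx in WQ_INDEXES},
                "Z": {idx: 3.0 for idx in WQ_INDEXES}}
        with pytest.raises(ValueError):
            correlation_matrix(self._stats(means),
                               WaterQualityTable(rows=rows))
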