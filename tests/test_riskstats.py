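"""Risk accounting: proportions, elevation bands, trends, period means."""

import numpy as np
import pandas as pd
import pytest

import eai_risk as er

SCHEME = er.reference_schemes()["eai_risk"]


def _class_raster(codes, mask=None):
    return er.Grid(np.asarray(codes, dtype=float), mask)


class TestClassProportions:
    def test_counting(self):
        codes = np.full((10, 10), 2.0)  # LERA
        codes.ravel()[:32] = 1.0        # 32 HERA cells
        props = er.class_proportions(_class_raster(codes), SCHEME)
        assert props.loc["HERA", "region"] == 32.0
        assert props.loc["LERA", "region"] == 68.0

    def test_single_class_is_100(self):
        props = er.class_proportions(_class_raster(np.full((5, 5), 4.0)),
                                     SCHEME)
        assert props.loc["PERA", "region"] == 100.0
        assert props.drop("PERA").sum().sum() == 0.0

    def test_masked_cells_excluded(self):
        codes = np.zeros((4, 4))
        codes[:2] = 4.0
        mask = np.zeros((4, 4), dtype=bool)
        mask[:2] = True  # mask exactly the PERA half
        props = er.class_proportions(_class_raster(codes, mask), SCHEME)
        assert props.loc["HeERA", "region"] == 100.0


class TestBandProportions:
    def test_crafted_counts(self):
        # 6x6: top three rows at 2000 m all PERA; bottom three at 4500 m,
        # half HERA half HeERA
        dem = er.Grid(np.r_[np.full((3, 6), 2000.0),
                            np.full((3, 6), 4500.0)])
        codes = np.r_[np.full((3, 6), 4.0),
                      np.tile([1.0, 0.0, 1.0, 0.0, 1.0, 0.0], (3, 1))]
        props, share = er.band_proportions(_class_raster(codes), dem,
                                           SCHEME)
        assert props.loc["PERA", "<2300m"] == 100.0
        assert props.loc["HERA", "4400-5000m"] == 50.0
        assert props.loc["HeERA", "4400-5000m"] == 50.0
        assert share["<2300m"] == 50.0 and share["4400-5000m"] == 50.0

    def test_empty_band_reported_as_nan(self):
        dem = er.Grid(np.full((4, 4), 3000.0))
        props, share = er.band_proportions(
            _class_raster(np.zeros((4, 4))), dem, SCHEME)
        assert props["<2300m"].isna().all()
        assert props.loc["HeERA", "2300-3600m"] == 100.0

    def test_misaligned_inputs_rejected(self):
        dem = er.Grid(np.zeros((3, 3)))
        with pytest.raises(er.GridError, match="aligned"):
            er.band_proportions(_class_raster(np.zeros((4, 4))), dem,
                                SCHEME)

    def test_columns_sum_to_100(self, small_scene, tables):
        eai = er.compute_eai(er.compute_cqi(small_scene, tables),
                             er.compute_sqi(small_scene, tables),
                             er.compute_vqi(small_scene, tables))
        risk = er.classify_by_breaks(eai.grid, SCHEME)
        props, share = er.band_proportions(risk, small_scene["DEM"], SCHEME)
        sums = props.sum(axis=0, skipna=False).dropna()
        assert np.allclose(sums, 100.0, atol=1e-9)
        assert share.sum() == pytest.approx(100.0, abs=1e-6)


class TestChangeRates:
    def _table(self, pera, lera):
        rest = 100.0 - pera - lera
        return pd.DataFrame({"band": [pera, lera, rest, 0.0, 0.0]},
                            index=["PERA", "LERA", "LeERA", "HERA",
                                   "HeERA"])

    def test_identical_tables_zero_change(self):
        t = self._table(50.0, 30.0)
        assert (er.change_rates(t, t) == 0).all().all()

    def test_differences_sum_to_zero_per_stratum(self):
        d = er.change_rates(self._table(50.0, 30.0),
                            self._table(40.0, 45.0))
        assert d["band"].sum() == pytest.approx(0.0, abs=1e-12)

    def test_potential_risk_share_drop(self):
        # a crafted pair: potential-risk share 93.03 -> 90.51 percent
        d = er.change_rates(self._table(93.03, 2.0),
                            self._table(90.51, 2.0))
        assert d.loc["PERA", "band"] == pytest.approx(-2.52)

    def test_mismatched_tables_rejected(self):
        t1 = self._table(50.0, 30.0)
        t2 = t1.copy()
        t2.index = ["a", "b", "c", "d", "e"]
        with pytest.raises(ValueError, match="mismatched"):
            er.change_rates(t1, t2)


class TestEnsembleMean:
    def _series(self, vals, member="m1", years=None):
        years = np.arange(2021, 2021 + len(vals)) if years is None else years
        return er.ScenarioSeries("SSP126", member, years, vals, "Pr", "mm")

    def test_symmetric_members_cancel(self):
        v = np.arange(5.0)
        out = er.ensemble_mean([self._series(v), self._series(-v, "m2")])
        np.testing.assert_array_equal(out.values, 0.0)

    def test_single_member_identity(self):
        v = np.arange(5.0)
        np.testing.assert_array_equal(er.ensemble_mean(
            [self._series(v)]).values, v)

    def test_constant_members_average(self):
        members = [self._series(np.full(4, c), f"m{c}") for c in (1, 2, 3)]
        np.testing.assert_array_equal(er.ensemble_mean(members).values, 2.0)

    def test_mismatched_years_rejected(self):
        a = self._series(np.zeros(3))
        b = self._series(np.zeros(3), "m2", years=np.array([1, 2, 3]))
        with pytest.raises(ValueError, match="year"):
            er.ensemble_mean([a, b])


class TestTrendRate:
    def test_noiseless_line_recovered_exactly(self):
        years = np.arange(2021, 2101)
        s = er.ScenarioSeries("SSP585", "m", years,
                              0.062 * (years - 2021), "T", "degC")
        rate, r2 = er.trend_rate(s)
        assert rate == pytest.approx(0.62, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_series_convention(self):
        s = er.ScenarioSeries("SSP126", "m", np.arange(2021, 2031),
                              np.full(10, 3.0), "Pr", "mm")
        assert er.trend_rate(s) == (0.0, 0.0)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(0)
        years = np.arange(2021, 2101).astype(float)
        y = 5 + 0.1 * years + rng.normal(0, 3, len(years))
        s = er.ScenarioSeries("SSP126", "m", years.astype(int), y, "Pr",
                              "mm")
        rate, _ = er.trend_rate(s)
        x = years - years.mean()
        closed = (x @ (y - y.mean())) / (x @ x) * 10
        assert rate == pytest.approx(closed, rel=1e-12)

    def test_mean_of_slopes_equals_slope_of_means(self):
        rng = np.random.default_rng(2)
        years = np.arange(2021, 2061)
        members = [er.ScenarioSeries("SSP245", f"m{i}", years,
                                     rng.normal(0, 5, len(years)), "Pr",
                                     "mm") for i in range(4)]
        mean_rate = np.mean([er.trend_rate(m)[0] for m in members])
        ens_rate, _ = er.trend_rate(er.ensemble_mean(members))
        assert ens_rate == pytest.approx(mean_rate, rel=1e-10)

    def test_too_short_series_rejected(self):
        s = er.ScenarioSeries("SSP126", "m", [2021, 2022], [1.0, 2.0],
                              "Pr", "mm")
        with pytest.raises(ValueError, match="3 years"):
            er.trend_rate(s)


class TestPeriodMean:
    def _rasters(self, years, value_fn):
        return {y: er.Grid(np.full((2, 2), value_fn(y))) for y in years}

    def test_identical_years_identity(self):
        rasters = self._rasters(range(2021, 2041), lambda y: 4.5)
        out = er.period_mean_stack(rasters, "2021-2040")
        np.testing.assert_array_equal(out.values, 4.5)

    def test_two_year_toy_mean(self):
        rasters = {2021: er.Grid(np.full((1, 1), 2.0)),
                   2022: er.Grid(np.full((1, 1), 4.0))}
        out = er.period_mean_stack(rasters, (2021, 2022))
        assert out.values[0, 0] == 3.0

    def test_missing_years_listed(self):
        rasters = self._rasters(range(2021, 2040), lambda y: 1.0)
        with pytest.raises(ValueError, match="2040"):
            er.period_mean_stack(rasters, "2021-2040")

    def test_masked_year_masks_the_mean(self):
        a = er.Grid(np.full((1, 2), 2.0))
        b = er.Grid(np.full((1, 2), 4.0),
                    np.array([[True, False]]))
        out = er.period_mean_stack({2021: a, 2022: b}, (2021, 2022))
        assert out.nodata_mask[0, 0] and not out.nodata_mask[0, 1]


def test_series_csv_round_trip(tmp_path):
    years = np.arange(2021, 2031)
    orig = [er.ScenarioSeries("SSP370", f"m{i}", years,
                              np.linspace(i, i + 5, 10), "T", "degC")
            for i in range(3)]
    df = er.series_to_frame(orig)
    p = tmp_path / "series.csv"
    df.to_csv(p, index=False)
    back = er.frame_to_series(pd.read_csv(p))
    assert len(back) == 3
    for a, b in zip(orig, back):
        assert a.member_id == b.member_id
        np.testing.assert_allclose(a.values, b.values)
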