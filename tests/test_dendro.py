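"""BAI conversion, spline detrending, dating QC, chronologies, and
climate-growth bootstrap correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from treegs.climate import MonthlyIndexTable
from treegs.dendro import (
    Chronology,
    RingSeries,
    bai_to_width,
    bootstrap_climate_correlation,
    build_chronology,
    check_dating,
    detrend_spline,
    smoothing_spline,
    tukey_biweight_mean,
    width_to_bai,
)
from treegs.rwl import read_rwl, write_rwl


class TestBAI:
    def test_hand_example_two_unit_widths(self):
        s = RingSeries("t", 2000, [1.0, 1.0], kind="width")
        bai = width_to_bai(s, r0=0.0)
        assert np.allclose(bai.values, [np.pi, 3 * np.pi])

    def test_single_width_is_circle_area(self):
        bai = width_to_bai(RingSeries("t", 2000, [2.0], kind="width"))
        assert bai.values[0] == pytest.approx(np.pi * 4.0)

    def test_telescoping_sum(self):
        widths = np.array([0.5, 1.2, 0.8, 2.0])
        bai = width_to_bai(RingSeries("t", 2000, widths, kind="width"), r0=3.0)
        assert bai.values.sum() == pytest.approx(
            np.pi * (3.0 + widths.sum()) ** 2 - np.pi * 9.0
        )

    @settings(deadline=None, max_examples=40)
    @given(
        widths=st.lists(st.floats(0.05, 8.0), min_size=1, max_size=40),
        r0=st.floats(0.0, 10.0),
    )
    def test_round_trip_exact(self, widths, r0):
        s = RingSeries("t", 1990, np.array(widths), kind="width")
        back = bai_to_width(width_to_bai(s, r0=r0), r0=r0)
        assert np.abs(back.values - s.values).max() < 1e-9

    def test_nonpositive_width_rejected_with_year(self):
        with pytest.raises(ValueError, match="1993"):
            RingSeries("t", 1990, [1.0, 1.0, 1.0, 0.0], kind="width")


class TestDetrend:
    def test_constant_series_gives_unit_index(self):
        s = RingSeries("t", 2000, np.full(25, 10.0), kind="bai")
        idx, curve = detrend_spline(s)
        assert np.allclose(idx.values, 1.0)
        assert np.allclose(curve, 10.0)

    def test_linear_trend_interpolating_limit(self):
        s = RingSeries("t", 2000, np.linspace(5, 50, 20), kind="bai")
        idx, _ = detrend_spline(s, f=1.0)
        assert np.allclose(idx.values, 1.0)

    def test_linear_trend_any_f(self):
        # straight lines are in the spline's penalty null space
        s = RingSeries("t", 2000, np.linspace(5, 50, 20), kind="bai")
        idx, _ = detrend_spline(s, f=0.5)
        assert np.allclose(idx.values, 1.0, atol=1e-8)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        vals = np.exp(rng.normal(3, 0.2, 30))
        i1, _ = detrend_spline(RingSeries("t", 2000, vals, kind="bai"))
        i2, _ = detrend_spline(RingSeries("t", 2000, 7.3 * vals, kind="bai"))
        assert np.abs(i1.values - i2.values).max() < 1e-8

    def test_mean_index_near_one_over_simulated_series(self):
        rng = np.random.default_rng(42)
        means = []
        ages = np.arange(1, 20)
        trend = 1500.0 / (1.0 + np.exp(-(ages - 8) / 3.0))
        for _ in range(100):
            vals = trend * np.exp(rng.normal(0, 0.1, len(ages)))
            idx, _ = detrend_spline(RingSeries("t", 1997, vals, kind="bai"))
            means.append(idx.values.mean())
        assert all(0.95 <= m <= 1.05 for m in means)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            detrend_spline(RingSeries("t", 2000, [1.0, 2.0, 3.0], kind="bai"))

    def test_frequency_response_at_design_wavelength(self):
        # a pure sinusoid at the design wavelength should be attenuated to ~f
        n, wl, f = 400, 40.0, 0.7
        x = np.arange(n)
        y = np.sin(2 * np.pi * x / wl)
        s = smoothing_spline(y, f=f, wavelength=wl)
        interior = slice(60, n - 60)  # ignore boundary effects
        gain = np.sqrt(np.mean(s[interior] ** 2) / np.mean(y[interior] ** 2))
        assert gain == pytest.approx(f, abs=0.03)


class TestDating:
    def test_duplicate_of_master_not_flagged(self):
        rng = np.random.default_rng(1)
        base = 1.0 + 0.2 * np.sin(np.arange(30)) + rng.normal(0, 0.02, 30)
        series = [RingSeries(f"t{i}", 2000, base + rng.normal(0, 0.01, 30), kind="index")
                  for i in range(5)]
        flags = check_dating(series)
        assert not flags["flagged"].any()
        assert (flags["master_correlation"] > 0.9).all()

    def test_shifted_series_in_sawtooth_flagged(self):
        saw = np.tile([0.8, 1.2], 15)
        series = [RingSeries(f"t{i}", 2000, saw, kind="index") for i in range(4)]
        shifted = RingSeries("bad", 2000, np.roll(saw, 1), kind="index")
        flags = check_dating(series + [shifted]).set_index("tree_id")
        assert bool(flags.loc["bad", "flagged"])
        assert flags.loc["bad", "master_correlation"] < 0.2
        assert not flags.loc[[f"t{i}" for i in range(4)], "flagged"].any()

    def test_insufficient_overlap_flagged(self):
        a = RingSeries("a", 2000, np.ones(20) + np.arange(20) * 0.01, kind="index")
        b = RingSeries("b", 2000, np.ones(20) - np.arange(20) * 0.01, kind="index")
        c = RingSeries("c", 2030, np.ones(10), kind="index")  # no overlap
        flags = check_dating([a, b, c]).set_index("tree_id")
        assert flags.loc["c", "reason"] == "insufficient overlap"

    def test_fewer_than_three_series_rejected(self):
        s = RingSeries("a", 2000, np.ones(5), kind="index")
        with pytest.raises(ValueError, match="3 series"):
            check_dating([s, s])


class TestChronology:
    def test_identical_series_reproduced(self):
        vals = np.array([1.0, 1.1, 0.9, 1.05])
        series = [RingSeries(f"t{i}", 2000, vals, kind="index") for i in range(6)]
        chron = build_chronology(series)
        assert np.allclose(chron.data["index"].values, vals)
        assert (chron.data["depth"] == 6).all()

    def test_outlier_resistance(self):
        rng = np.random.default_rng(0)
        series = [
            RingSeries(f"t{i}", 2000, 1.0 + rng.normal(0, 0.05, 10), kind="index")
            for i in range(10)
        ]
        clean_mean = np.mean([s.values[4] for s in series])
        series[0].values[4] = 50.0  # gross outlier in one year
        chron = build_chronology(series)
        robust = chron.value_in(2004)
        assert abs(robust - clean_mean) / clean_mean < 0.02

    def test_depth_accounting(self):
        s1 = RingSeries("a", 2000, np.ones(10), kind="index")
        s2 = RingSeries("b", 2005, np.ones(10), kind="index")
        chron = build_chronology([s1, s2])
        assert chron.data["depth"].sum() == 20

    def test_min_depth_fraction_subsets_years(self):
        s1 = RingSeries("a", 2000, np.ones(10), kind="index")
        s2 = RingSeries("b", 2005, np.ones(10), kind="index")
        chron = build_chronology([s1, s2], min_depth_fraction=0.75)
        # only the overlap years reach 75% of the 2 series
        assert set(chron.years) == set(range(2005, 2010))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no series"):
            build_chronology([])

    def test_biweight_matches_mean_for_clean_data(self):
        vals = np.array([0.9, 1.0, 1.1, 1.05, 0.95])
        assert tukey_biweight_mean(vals) == pytest.approx(vals.mean(), abs=0.01)


def _climate_table(years, month_values):
    rows = []
    for y in years:
        for m, v in month_values(y).items():
            rows.append({"year": y, "month": m, "dc_raw": v})
    return MonthlyIndexTable(pd.DataFrame(rows))


class TestBootstrapCorrelation:
    def test_exact_negative_relationship(self):
        years = list(range(2000, 2020))
        rng = np.random.default_rng(0)
        dc = {y: rng.uniform(100, 300) for y in years}
        clim = _climate_table(years, lambda y: {7: dc[y]})
        chron = Chronology(
            pd.DataFrame({"year": years, "index": [-dc[y] for y in years], "depth": 10})
        )
        out = bootstrap_climate_correlation(chron, clim, months=(7,), lags=("current",), seed=1)
        row = out.iloc[0]
        assert row["r"] == pytest.approx(-1.0)
        assert bool(row["significant"])

    def test_previous_lag_alignment(self):
        # growth equals last year's July DC exactly: only the previous-year
        # lag shows the perfect correlation
        years = list(range(2000, 2020))
        rng = np.random.default_rng(3)
        dc = {y: rng.uniform(100, 300) for y in years}
        clim = _climate_table(years, lambda y: {7: dc[y]})
        chron = Chronology(
            pd.DataFrame(
                {"year": years[1:], "index": [dc[y - 1] for y in years[1:]], "depth": 5}
            )
        )
        out = bootstrap_climate_correlation(
            chron, clim, months=(7,), lags=("previous", "current"), seed=1
        ).set_index("lag")
        assert out.loc["previous", "r"] == pytest.approx(1.0)
        assert abs(out.loc["current", "r"]) < 0.9

    def test_type_one_error_rate(self):
        years = list(range(2000, 2020))
        sig = 0
        n_rep = 60
        for rep in range(n_rep):
            rng = np.random.default_rng(rep)
            clim = _climate_table(years, lambda y: {7: rng.uniform(100, 300)})
            chron = Chronology(
                pd.DataFrame({"year": years, "index": rng.normal(1, 0.1, len(years)),
                              "depth": 10})
            )
            out = bootstrap_climate_correlation(
                chron, clim, months=(7,), lags=("current",), n_boot=400, seed=rep
            )
            sig += int(out["significant"].iloc[0])
        assert sig / n_rep <= 0.12

    def test_ci_contains_estimate_and_shrinks_with_years(self):
        widths = {}
        for n_years in (10, 25):
            w = []
            for rep in range(30):
                rng = np.random.default_rng(1000 * n_years + rep)
                years = list(range(2000, 2000 + n_years))
                dcv = {y: rng.uniform(100, 300) for y in years}
                clim = _climate_table(years, lambda y: {7: dcv[y]})
                growth = [1 - 0.002 * dcv[y] + rng.normal(0, 0.05) for y in years]
                chron = Chronology(
                    pd.DataFrame({"year": years, "index": growth, "depth": 10})
                )
                out = bootstrap_climate_correlation(
                    chron, clim, months=(7,), lags=("current",), n_boot=300, seed=rep
                ).iloc[0]
                assert out["ci_low"] <= out["r"] <= out["ci_high"]
                w.append(out["ci_high"] - out["ci_low"])
            widths[n_years] = np.mean(w)
        assert widths[25] < widths[10]

    def test_insufficient_overlap_errors(self):
        years = list(range(2000, 2005))
        clim = _climate_table(years, lambda y: {7: 100.0})
        chron = Chronology(pd.DataFrame({"year": years, "index": 1.0, "depth": 3}))
        with pytest.raises(ValueError, match="overlapping"):
            bootstrap_climate_correlation(chron, clim, months=(7,), lags=("current",))


class TestRWL:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        series = {
            "TREE001": (1995, np.round(rng.uniform(0.3, 5.0, 23), 2)),
            "TREE002": (2001, np.round(rng.uniform(0.3, 5.0, 11), 2)),
        }
        path = tmp_path / "site.rwl"
        write_rwl(path, series)
        back = read_rwl(path)
        for sid, (fy, vals) in series.items():
            assert back[sid][0] == fy
            assert np.allclose(back[sid][1], vals, atol=1e-9)

    def test_thousandths_dialect(self, tmp_path):
        path = tmp_path / "t.rwl"
        path.write_text("CORE0001 2000   123   456  -9999\n")
        back = read_rwl(path)
        assert np.allclose(back["CORE0001"][1], [0.123, 0.456])
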