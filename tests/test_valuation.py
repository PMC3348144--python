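"""Plot valuation: price averaging, conversion arithmetic, log transform."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from timberkrige.valuation import (
    average_prices,
    log_transform,
    survey_diagnostics,
    value_plots,
)


class TestAveragePrices:
    def test_two_year_mean(self):
        raw = pd.DataFrame(
            {"genus": ["g", "g"], "year": [2006, 2007], "usd_per_m3": [100.0, 300.0]}
        )
        out = average_prices(raw)
        assert out.loc[0, "price_usd_per_m3"] == 200.0

    def test_single_year_identity(self):
        raw = pd.DataFrame({"genus": ["g"], "year": [2006], "usd_per_m3": [158.0]})
        assert average_prices(raw).loc[0, "price_usd_per_m3"] == 158.0

    def test_genus_without_rows_excluded_with_warning(self, caplog):
        raw = pd.DataFrame(
            {"genus": ["a", "b"], "year": [2006, 2006], "usd_per_m3": [10.0, 20.0]}
        )
        raw.attrs["genera"] = ["a", "b", "c"]
        with caplog.at_level("WARNING"):
            out = average_prices(raw)
        assert len(out) == 2
        assert "c" in caplog.text

    def test_nonpositive_price_rejected(self):
        raw = pd.DataFrame({"genus": ["g"], "year": [2006], "usd_per_m3": [0.0]})
        with pytest.raises(ValueError):
            average_prices(raw)


class TestValuePlots:
    def test_direct_arithmetic(self):
        survey = pd.DataFrame(
            {"plot_id": [0], "x_km": [0.0], "y_km": [0.0], "genus": ["g"], "volume_m3": [10.0]}
        )
        prices = pd.DataFrame({"genus": ["g"], "price_usd_per_m3": [100.0]})
        out = value_plots(survey, prices, conversion=0.35)
        assert out.loc[0, "total_usd_ha"] == pytest.approx(350.0)

    def test_conversion_ratio_exact(self, small_survey, small_prices):
        converted = value_plots(small_survey, small_prices, conversion=0.35)
        unconverted = value_plots(small_survey, small_prices, conversion=1.0)
        ratio = converted["total_usd_ha"] / unconverted["total_usd_ha"]
        assert np.allclose(ratio[unconverted["total_usd_ha"] > 0], 0.35)

    def test_duplicate_plot_genus_rows_summed(self, small_survey, small_prices):
        out = value_plots(small_survey, small_prices, conversion=1.0)
        # plot 0 has two Hymenaea records (4 + 6 m3) at 569 US$/m3
        assert out.set_index("plot_id").loc[0, "total_usd_ha"] == pytest.approx(10 * 569)

    def test_genus_missing_price_dropped_with_warning(self, small_survey, caplog):
        prices = pd.DataFrame({"genus": ["Hymenaea"], "price_usd_per_m3": [569.0]})
        with caplog.at_level("WARNING"):
            out = value_plots(small_survey, prices)
        assert "Swartzia" in caplog.text
        assert out.set_index("plot_id").loc[2, "total_usd_ha"] == 0.0

    def test_negative_volume_rejected(self, small_prices):
        survey = pd.DataFrame(
            {"plot_id": [0], "x_km": [0.0], "y_km": [0.0], "genus": ["Goupia"], "volume_m3": [-1.0]}
        )
        with pytest.raises(ValueError, match="negative volume"):
            value_plots(survey, small_prices)

    def test_disjoint_genera_rejected(self, small_survey):
        prices = pd.DataFrame({"genus": ["Nosuch"], "price_usd_per_m3": [100.0]})
        with pytest.raises(ValueError, match="no surveyed genus"):
            value_plots(small_survey, prices)

    def test_case_insensitive_genus_match(self, small_prices):
        survey = pd.DataFrame(
            {"plot_id": [0], "x_km": [0.0], "y_km": [0.0], "genus": [" hymenaea "], "volume_m3": [1.0]}
        )
        out = value_plots(survey, small_prices, conversion=1.0)
        assert out.loc[0, "total_usd_ha"] == pytest.approx(569.0)

    def test_total_is_sum_of_genus_columns(self, small_survey, small_prices):
        out = value_plots(small_survey, small_prices)
        cols = [c for c in out.columns if c.startswith("value_")]
        assert np.allclose(out[cols].sum(axis=1), out["total_usd_ha"])

    @given(k=st.floats(min_value=0.01, max_value=100.0, allow_nan=False))
    def test_scale_equivariance(self, k):
        # multiplying volumes by k multiplies totals by k, shifts log10 by log10(k)
        survey = pd.DataFrame(
            {
                "plot_id": [0, 1],
                "x_km": [0.0, 1.0],
                "y_km": [0.0, 1.0],
                "genus": ["g", "g"],
                "volume_m3": [2.0, 7.0],
            }
        )
        prices = pd.DataFrame({"genus": ["g"], "price_usd_per_m3": [100.0]})
        base = log_transform(value_plots(survey, prices))
        scaled_survey = survey.assign(volume_m3=survey["volume_m3"] * k)
        scaled = log_transform(value_plots(scaled_survey, prices))
        assert np.allclose(scaled["total_usd_ha"], k * base["total_usd_ha"])
        assert np.allclose(scaled["log10_total"], base["log10_total"] + np.log10(k))

    def test_split_volume_invariance(self, small_prices):
        # splitting one genus record across rows leaves the total unchanged
        whole = pd.DataFrame(
            {"plot_id": [0], "x_km": [0.0], "y_km": [0.0], "genus": ["Goupia"], "volume_m3": [9.0]}
        )
        split = pd.DataFrame(
            {
                "plot_id": [0, 0, 0],
                "x_km": [0.0] * 3,
                "y_km": [0.0] * 3,
                "genus": ["Goupia"] * 3,
                "volume_m3": [4.0, 3.0, 2.0],
            }
        )
        a = value_plots(whole, small_prices)["total_usd_ha"]
        b = value_plots(split, small_prices)["total_usd_ha"]
        assert np.allclose(a, b)


class TestLogTransform:
    def test_exact_power_of_ten(self):
        df = pd.DataFrame(
            {"plot_id": [0], "x_km": [0.0], "y_km": [0.0], "total_usd_ha": [1000.0]}
        )
        assert log_transform(df).loc[0, "log10_total"] == pytest.approx(3.0)

    def test_exclude_policy_drops_zero_plots(self):
        df = pd.DataFrame(
            {"plot_id": [0, 1], "x_km": [0.0, 1.0], "y_km": [0.0, 1.0],
             "total_usd_ha": [0.0, 100.0]}
        )
        out = log_transform(df, policy="exclude")
        assert len(out) == 1
        assert out.attrs["n_retained"] == 1

    def test_offset_policy_keeps_all(self):
        df = pd.DataFrame(
            {"plot_id": [0, 1], "x_km": [0.0, 1.0], "y_km": [0.0, 1.0],
             "total_usd_ha": [0.0, 9.0]}
        )
        out = log_transform(df, policy="offset", epsilon=1.0)
        assert len(out) == 2
        assert out.loc[1, "log10_total"] == pytest.approx(1.0)

    def test_antilog_round_trip(self):
        df = pd.DataFrame(
            {"plot_id": [0, 1], "x_km": [0.0, 1.0], "y_km": [0.0, 1.0],
             "total_usd_ha": [17.0, 3150.0]}
        )
        out = log_transform(df)
        assert np.allclose(10 ** out["log10_total"], out["total_usd_ha"])

    def test_all_nonpositive_rejected(self):
        df = pd.DataFrame(
            {"plot_id": [0], "x_km": [0.0], "y_km": [0.0], "total_usd_ha": [0.0]}
        )
        with pytest.raises(ValueError):
            log_transform(df)


class TestDiagnostics:
    def test_single_genus_full_share(self):
        survey = pd.DataFrame(
            {"plot_id": [0, 1], "x_km": [0.0, 1.0], "y_km": [0.0, 1.0],
             "genus": ["g", "g"], "volume_m3": [1.0, 2.0]}
        )
        diag = survey_diagnostics(survey)
        assert diag.max_volume_share == pytest.approx(1.0)
        assert diag.max_share_genus == "g"

    def test_counts_and_volumes(self, small_survey):
        diag = survey_diagnostics(small_survey)
        per = diag.per_genus.set_index("genus")
        assert per.loc["Hymenaea", "n_locations"] == 2
        assert per.loc["Hymenaea", "total_volume_m3"] == pytest.approx(12.0)

    def test_empty_survey_rejected(self):
        with pytest.raises(ValueError):
            survey_diagnostics(pd.DataFrame(columns=["plot_id", "genus", "volume_m3"]))
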