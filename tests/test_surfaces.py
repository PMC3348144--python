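"""Grid prediction, back-transformation, masking, summaries."""

import numpy as np
import pytest

from timberkrige.kriging import KrigingConfig, ordinary_krige
from timberkrige.surfaces import (
    GridSpec,
    PredictionSurface,
    apply_mask,
    back_transform,
    grid_from_bounds,
    predict_grid,
    summarize,
)
from timberkrige.variogram import VariogramModel


@pytest.fixture
def model():
    return VariogramModel("spherical", nugget=0.0, partial_sill=1.0, range_km=40.0)


def flat_surface(value, n=4, se=0.1):
    grid = GridSpec(0, 0, 10, n, n)
    return PredictionSurface(
        grid=grid,
        pred_log10=np.full(grid.shape, float(value)),
        se_log10=np.full(grid.shape, se),
        mask=np.ones(grid.shape, dtype=bool),
    )


class TestGridSpec:
    def test_cell_centers_north_up(self):
        grid = GridSpec(0, 0, 10, 2, 2)
        centers = grid.cell_centers()
        # row-major from the top row: y = 15 first, then y = 5
        assert centers.tolist() == [[5, 15], [15, 15], [5, 5], [15, 5]]

    def test_grid_from_bounds_covers_points(self, rng):
        pts = rng.uniform(0, 97, (40, 2))
        grid = grid_from_bounds(pts, cell_size_km=10.0)
        assert grid.origin_x <= pts[:, 0].min()
        assert grid.origin_x + grid.n_cols * 10.0 >= pts[:, 0].max()

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(0, 0, 0.0, 5, 5)
        with pytest.raises(ValueError):
            GridSpec(0, 0, 1.0, 0, 5)


class TestPredictGrid:
    def test_single_cell_at_datum_is_exact(self, model):
        # 1x1 grid whose centre coincides with a datum; zero nugget
        grid = GridSpec(0, 0, 10, 1, 1)  # centre (5, 5)
        pts = np.array([[5.0, 5.0], [50.0, 50.0], [20.0, 0.0]])
        z = np.array([2.5, 3.0, 3.5])
        surf = predict_grid(pts, z, model, grid, KrigingConfig(neighborhood="all"))
        assert surf.pred_log10[0, 0] == pytest.approx(2.5, abs=1e-8)
        assert surf.se_log10[0, 0] == pytest.approx(0.0, abs=1e-6)

    def test_matches_per_cell_kriging_calls(self, rng, model):
        pts = rng.uniform(0, 100, (30, 2))
        z = rng.normal(size=30)
        grid = GridSpec(0, 0, 25, 4, 4)
        surf = predict_grid(pts, z, model, grid, KrigingConfig(neighborhood="all"))
        pred, se = ordinary_krige(
            pts, z, model, grid.cell_centers(), KrigingConfig(neighborhood="all")
        )
        assert np.allclose(surf.pred_log10.ravel(), pred)
        assert np.allclose(surf.se_log10.ravel(), se)


class TestBackTransform:
    def test_published_worked_example(self):
        # a log10 value of 4.10 with 35% sawn-wood recovery is ~US$4400/ha
        surf = back_transform(flat_surface(4.10), conversion=0.35)
        assert surf.value_usd_ha[0, 0] == pytest.approx(4400.0, rel=0.01)

    def test_power_of_ten_identity(self):
        surf = back_transform(flat_surface(3.0), conversion=1.0)
        assert surf.value_usd_ha[0, 0] == pytest.approx(1000.0)

    def test_inverse_pair_with_log_transform(self):
        for v in (17.0, 813.0, 3150.0):
            surf = back_transform(flat_surface(np.log10(v)), conversion=0.35)
            assert surf.value_usd_ha[0, 0] / v == pytest.approx(0.35)

    def test_bias_correction_increases_values(self):
        naive = back_transform(flat_surface(3.0, se=0.4), conversion=0.35)
        corrected = back_transform(flat_surface(3.0, se=0.4), conversion=0.35, bias_correct=True)
        assert np.all(corrected.value_usd_ha > naive.value_usd_ha)

    def test_summary_scales_linearly_with_conversion(self, rng):
        base = flat_surface(0.0)
        base.pred_log10 = rng.normal(3.0, 0.3, base.grid.shape)
        s1 = summarize(back_transform(base, conversion=0.35))
        s2 = summarize(back_transform(base, conversion=0.7))
        assert s2.mean_usd_ha == pytest.approx(2 * s1.mean_usd_ha)
        assert s2.max_usd_ha == pytest.approx(2 * s1.max_usd_ha)

    def test_invalid_conversion_rejected(self):
        with pytest.raises(ValueError):
            back_transform(flat_surface(3.0), conversion=0.0)


class TestMasking:
    def test_all_true_mask_identity(self, rng):
        surf = back_transform(flat_surface(3.0), conversion=0.35)
        surf.pred_log10 = rng.normal(3, 0.5, surf.grid.shape)
        surf = back_transform(surf, conversion=0.35)
        masked = apply_mask(surf, np.ones(surf.grid.shape, dtype=bool))
        assert summarize(masked).to_dict() == summarize(surf).to_dict()

    def test_removing_largest_cell_decreases_max(self, rng):
        surf = flat_surface(0.0)
        surf.pred_log10 = rng.normal(3, 0.5, surf.grid.shape)
        surf = back_transform(surf, conversion=0.35)
        peak = np.unravel_index(np.argmax(surf.value_usd_ha), surf.grid.shape)
        mask = np.ones(surf.grid.shape, dtype=bool)
        mask[peak] = False
        masked = apply_mask(surf, mask)
        assert summarize(masked).max_usd_ha < summarize(surf).max_usd_ha
        assert summarize(masked).min_usd_ha >= summarize(surf).min_usd_ha

    def test_all_false_mask_is_error(self):
        surf = back_transform(flat_surface(3.0), conversion=0.35)
        with pytest.raises(ValueError, match="empty surface"):
            apply_mask(surf, np.zeros(surf.grid.shape, dtype=bool))

    def test_grid_mismatch_is_error(self):
        surf = back_transform(flat_surface(3.0), conversion=0.35)
        with pytest.raises(ValueError, match="mask shape"):
            apply_mask(surf, np.ones((2, 2), dtype=bool))


class TestSummarize:
    def test_constant_surface_degenerate_summary(self):
        s = summarize(back_transform(flat_surface(2.0), conversion=1.0))
        assert s.mean_usd_ha == s.q025_usd_ha == s.q975_usd_ha == pytest.approx(100.0)

    def test_quantiles_match_sort_based_oracle(self):
        surf = flat_surface(0.0, n=10)
        vals = np.arange(1.0, 101.0).reshape(10, 10)
        surf.value_usd_ha = vals
        s = summarize(surf)
        srt = np.sort(vals.ravel())
        assert s.q025_usd_ha == pytest.approx(np.quantile(srt, 0.025))
        assert s.q975_usd_ha == pytest.approx(np.quantile(srt, 0.975))
        assert s.min_usd_ha == 1.0 and s.max_usd_ha == 100.0

    def test_left_concentrated_surface_pins_lower_quantile(self):
        # heavy mass at the low value: the lower 95% bound equals that value
        surf = flat_surface(0.0, n=10)
        vals = np.full(100, 5.0)
        vals[-3:] = [500.0, 900.0, 2000.0]
        surf.value_usd_ha = vals.reshape(10, 10)
        s = summarize(surf)
        assert s.q025_usd_ha == pytest.approx(5.0)
        assert s.q975_usd_ha > 5.0

    def test_not_back_transformed_rejected(self):
        with pytest.raises(ValueError):
            summarize(flat_surface(3.0))


class TestGenusVsTotalKriging:
    def test_sum_of_genus_surfaces_differs_from_total_surface(self, rng):
        # kriging is nonlinear through the log transform: anti-logged
        # genus-level maps summed != the map of kriged totals
        from timberkrige.synthetic import default_survey_config, simulate_survey
        from timberkrige.valuation import log_transform, value_plots
        from timberkrige.synthetic import default_price_table

        survey = simulate_survey(default_survey_config(seed=9, n_plots=300))
        valued = value_plots(survey, default_price_table())
        grid = grid_from_bounds(valued[["x_km", "y_km"]].to_numpy(), cell_size_km=500.0)
        model = VariogramModel("spherical", nugget=0.1, partial_sill=0.5, range_km=300.0)
        cfg = KrigingConfig()

        total = log_transform(valued)
        surf_total = back_transform(
            predict_grid(
                total[["x_km", "y_km"]].to_numpy(),
                total["log10_total"].to_numpy(),
                model, grid, cfg,
            ),
            conversion=0.35,
        )
        genus_sum = np.zeros(grid.shape)
        for col in [c for c in valued.columns if c.startswith("value_")]:
            sub = valued[valued[col] > 0]
            if len(sub) < 5:
                continue
            surf = back_transform(
                predict_grid(
                    sub[["x_km", "y_km"]].to_numpy(),
                    np.log10(sub[col].to_numpy()),
                    model, grid, cfg,
                ),
                conversion=0.35,
            )
            genus_sum += surf.value_usd_ha
        rel = np.abs(genus_sum - surf_total.value_usd_ha) / surf_total.value_usd_ha
        assert np.max(rel) > 0.01  # genuinely different surfaces
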