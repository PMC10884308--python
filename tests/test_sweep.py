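"""Prediction-matrix construction, curve prediction and slope extraction."""

import numpy as np
import pytest

import skatesense as sk
from skatesense.errors import DataError
from skatesense.sweep import FACTOR_COLUMN


class TestBuildSweepMatrix:
    def test_altitude_grid(self, skater_dataset):
        m = sk.build_sweep_matrix("altitude", skater_dataset)
        assert m.grid.shape == (500, 3)
        np.testing.assert_allclose(m.grid[0], [0.0, skater_dataset.t_con, skater_dataset.r_con])
        np.testing.assert_allclose(m.grid[-1], [1500.0, skater_dataset.t_con, skater_dataset.r_con])
        assert m.step == pytest.approx(1500 / 499)

    def test_race_freq_grid_holds_altitude_at_50(self, skater_dataset):
        m = sk.build_sweep_matrix("race_freq", skater_dataset)
        r_max = skater_dataset.ranges["race_index"][1]
        np.testing.assert_allclose(m.grid[0], [50.0, skater_dataset.t_con, 1.0])
        np.testing.assert_allclose(m.grid[-1], [50.0, skater_dataset.t_con, r_max])

    @pytest.mark.parametrize("factor", ["altitude", "ice_temp", "race_freq"])
    def test_non_swept_columns_are_constant(self, skater_dataset, factor):
        m = sk.build_sweep_matrix(factor, skater_dataset)
        swept_col = ("altitude", "ice_temp", "race_index").index(FACTOR_COLUMN[factor])
        for j in range(3):
            if j != swept_col:
                assert np.ptp(m.grid[:, j]) == 0.0

    def test_unknown_factor_and_degenerate_range_error(self, skater_dataset):
        with pytest.raises(DataError):
            sk.build_sweep_matrix("humidity", skater_dataset)
        stats = {"t_con": -7.0, "r_con": 3.0,
                 "ranges": {"altitude": (0, 1500), "ice_temp": (-7.0, -7.0), "race_index": (1, 10)}}
        with pytest.raises(DataError, match="ice_temp"):
            sk.build_sweep_matrix("ice_temp", stats)


class TestPredictCurve:
    def test_constant_stub_propagates_t_ave(self, skater_dataset, affine_stub):
        norm = skater_dataset.normalization_spec()
        # choose the scaled constant that de-normalizes to t_rel = 1
        const = norm.scale("t_rel", 1.0)
        matrix = sk.build_sweep_matrix("altitude", skater_dataset)
        y = sk.predict_curve(affine_stub(bias=float(const)), matrix, norm, t_ave=70.0)
        np.testing.assert_allclose(y, 70.0, rtol=1e-12)

    def test_linear_stub_has_closed_form_slope(self, skater_dataset, affine_stub):
        norm = skater_dataset.normalization_spec()
        c = 0.3
        matrix = sk.build_sweep_matrix("altitude", skater_dataset)
        y = sk.predict_curve(affine_stub(bias=0.2, coeffs=(c, 0, 0)), matrix, norm,
                             t_ave=skater_dataset.t_ave)
        y_lo, y_hi = norm.ranges["t_rel"]
        expected = c * (y_hi - y_lo) * skater_dataset.t_ave / 1500.0 * 1000.0  # s/km
        assert sk.slope_of_curve(y, matrix) == pytest.approx(expected, rel=1e-10)

    def test_out_of_range_grid_is_an_error(self, skater_dataset, affine_stub):
        norm = skater_dataset.normalization_spec()
        matrix = sk.build_sweep_matrix("altitude", skater_dataset)
        matrix.grid[0, 0] = -5.0
        with pytest.raises(DataError):
            sk.predict_curve(affine_stub(), matrix, norm, t_ave=70.0)

    def test_trained_models_predict_near_t_ave(self, skater_dataset, small_ensemble):
        norm = skater_dataset.normalization_spec()
        matrix = sk.build_sweep_matrix("altitude", skater_dataset)
        y = sk.predict_curve(small_ensemble.retained[0], matrix, norm, skater_dataset.t_ave)
        assert np.all(np.abs(y / skater_dataset.t_ave - 1) < 0.1)


class TestSlopeOfCurve:
    def test_flat_curve_is_zero(self, skater_dataset):
        matrix = sk.build_sweep_matrix("ice_temp", skater_dataset)
        assert sk.slope_of_curve(np.full(500, 70.0), matrix) == 0.0

    def test_linear_curve_recovers_coefficient_in_s_per_km(self, skater_dataset):
        matrix = sk.build_sweep_matrix("altitude", skater_dataset)
        y = 70.0 - 0.0005 * matrix.swept_values  # s per metre
        assert sk.slope_of_curve(y, matrix) == pytest.approx(-0.5, abs=1e-10)

    def test_decreasing_curve_gives_negative_slope(self, skater_dataset):
        matrix = sk.build_sweep_matrix("altitude", skater_dataset)
        y = 70.0 - 1e-4 * matrix.swept_values
        assert sk.slope_of_curve(y, matrix) < 0

    def test_endpoint_method_on_linear_curve_matches_ols(self, skater_dataset):
        matrix = sk.build_sweep_matrix("race_freq", skater_dataset)
        y = 70.0 + 0.02 * matrix.swept_values
        ols = sk.slope_of_curve(y, matrix, method="ols")
        fd = sk.slope_of_curve(y, matrix, method="endpoints")
        assert ols == pytest.approx(fd, rel=1e-9) == pytest.approx(0.02, rel=1e-9)


class TestAggregateSlopes:
    def test_mean_of_two(self):
        K, sd, counts, edges = sk.aggregate_slopes([-0.4, -0.6])
        assert K == pytest.approx(-0.5)
        assert counts.sum() == 2

    def test_identical_slopes_reproduce_themselves(self):
        K, sd, *_ = sk.aggregate_slopes([0.7] * 5)
        assert K == 0.7 and sd == 0.0

    def test_empty_is_an_error(self):
        with pytest.raises(DataError):
            sk.aggregate_slopes([])

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        k = rng.normal(-0.5, 0.1, 200)
        K1, *_ = sk.aggregate_slopes(k)
        K2, *_ = sk.aggregate_slopes(k[::-1].copy())
        assert K1 == pytest.approx(K2, rel=1e-12)

    def test_clt_recovery_of_population_mean(self):
        rng = np.random.default_rng(42)
        k = rng.normal(-0.5, 0.1, 200)
        K, *_ = sk.aggregate_slopes(k)
        assert abs(K - (-0.5)) < 3 * 0.1 / np.sqrt(200)


def test_additive_stub_slopes_do_not_cross_contaminate(skater_dataset, affine_stub):
    """For an additive model, each sweep recovers only its own coefficient."""
    norm = skater_dataset.normalization_spec()
    coeffs = (0.25, -0.15, 0.05)  # scaled-space marginal effects
    net = affine_stub(bias=0.4, coeffs=coeffs)
    y_lo, y_hi = norm.ranges["t_rel"]
    for factor, c in zip(("altitude", "ice_temp", "race_freq"), coeffs):
        matrix = sk.build_sweep_matrix(factor, skater_dataset)
        y = sk.predict_curve(net, matrix, norm, skater_dataset.t_ave)
        col = FACTOR_COLUMN[factor]
        lo, hi = norm.ranges[col]
        expected = c * (y_hi - y_lo) * skater_dataset.t_ave / (hi - lo)
        if factor == "altitude":
            expected *= 1000.0
        assert sk.slope_of_curve(y, matrix) == pytest.approx(expected, rel=1e-9)
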