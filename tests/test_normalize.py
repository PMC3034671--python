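"""Normalization methods: control scaling, Z-score, median polish/B-score,
well correction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from htsqc import (
    ControlStats,
    DegenerateDataError,
    PlateGrid,
    assay_from_array,
    bscore_plate,
    median_polish,
    normalized_percent_inhibition,
    percent_of_control,
    well_correction,
    zscore_plate,
)


class TestControlScaling:
    def test_percent_of_control_direct(self):
        p = PlateGrid(np.full((2, 2), 50.0))
        out = percent_of_control(p, ControlStats(mu_pos=100.0))
        np.testing.assert_allclose(out.values, 0.5)

    def test_percent_of_control_zero_mu_pos(self):
        with pytest.raises(DegenerateDataError):
            percent_of_control(PlateGrid(np.ones((2, 2))), ControlStats(mu_pos=0.0))

    def test_npi_anchor_points_and_direct_value(self):
        ctrl = ControlStats(mu_pos=120.0, mu_neg=20.0)
        p = PlateGrid(np.array([[20.0, 120.0], [30.0, 70.0]]))
        out = normalized_percent_inhibition(p, ctrl)
        np.testing.assert_allclose(
            out.values, [[0.0, 1.0], [0.1, 0.5]], atol=1e-15
        )

    def test_npi_equal_controls_rejected(self):
        with pytest.raises(DegenerateDataError):
            normalized_percent_inhibition(
                PlateGrid(np.ones((2, 2))), ControlStats(mu_pos=5.0, mu_neg=5.0)
            )


class TestZScore:
    def test_hand_example(self):
        out = zscore_plate(PlateGrid(np.array([[0.0, 0.0], [2.0, 2.0]])))
        np.testing.assert_allclose(
            out.values, [[-0.8660254, -0.8660254], [0.8660254, 0.8660254]]
        )

    def test_output_mean_zero_sd_one(self, masked_plate):
        out = zscore_plate(masked_plate)
        vv = out.valid_values
        assert vv.mean() == pytest.approx(0.0, abs=1e-12)
        assert vv.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_constant_plate_rejected(self):
        with pytest.raises(DegenerateDataError):
            zscore_plate(PlateGrid(np.full((3, 3), 2.0)))

    def test_affine_methods_preserve_rank_order(self, small_plate):
        order = np.argsort(small_plate.valid_values)
        for out in (
            zscore_plate(small_plate),
            percent_of_control(small_plate, ControlStats(mu_pos=3.0)),
            normalized_percent_inhibition(
                small_plate, ControlStats(mu_pos=2.0, mu_neg=-1.0)
            ),
        ):
            np.testing.assert_array_equal(np.argsort(out.valid_values), order)


class TestMedianPolish:
    def test_exactly_additive_plate_has_zero_residuals(self):
        # x[i, j] = 10 + r_i + c_j with r = (0, 2), c = (0, 1, 3)
        p = PlateGrid(np.array([[10.0, 11.0, 13.0], [12.0, 13.0, 15.0]]))
        res = median_polish(p)
        np.testing.assert_allclose(res.residuals, 0.0, atol=1e-12)
        assert res.converged

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_reconstruction_identity_and_residual_medians(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((6, 8)) > 0.15
        mask[:, :2] = True
        mask[:2, :] = True
        p = PlateGrid(rng.standard_normal((6, 8)) * 3, mask)
        res = median_polish(p)
        recon = res.fitted() + res.residuals
        np.testing.assert_allclose(recon[p.mask], p.values[p.mask], atol=1e-9)
        masked_resid = np.where(p.mask, res.residuals, np.nan)
        np.testing.assert_allclose(
            np.nanmedian(masked_resid, axis=1), 0.0, atol=1e-5
        )
        np.testing.assert_allclose(
            np.nanmedian(masked_resid, axis=0), 0.0, atol=1e-5
        )

    def test_masked_wells_do_not_affect_polish(self, masked_plate):
        res1 = median_polish(masked_plate)
        tampered = masked_plate.copy()
        tampered.values[~tampered.mask] = 99.0
        res2 = median_polish(tampered)
        np.testing.assert_array_equal(
            res1.residuals[masked_plate.mask], res2.residuals[masked_plate.mask]
        )


class TestBScore:
    def test_additive_plate_is_degenerate(self):
        p = PlateGrid(np.array([[10.0, 11.0, 13.0], [12.0, 13.0, 15.0]]))
        with pytest.raises(DegenerateDataError):
            bscore_plate(p)

    def test_known_residuals_mad_one(self):
        # plate whose polish leaves residuals {-2,-1,0,1,2} pattern per row:
        # a pure-noise matrix with zero row/col effects after centering
        resid = np.array([[-2.0, -1.0, 0.0, 1.0, 2.0],
                          [2.0, 1.0, 0.0, -1.0, -2.0],
                          [-1.0, 2.0, 0.0, -2.0, 1.0],
                          [1.0, -2.0, 0.0, 2.0, -1.0]])
        p = PlateGrid(resid)
        out = bscore_plate(p)
        # residual median 0, MAD > 0: B-scores are residuals / MAD
        res = median_polish(p)
        mad = np.median(np.abs(res.residuals - np.median(res.residuals)))
        np.testing.assert_allclose(out.values, res.residuals / mad)

    def test_bscore_median_near_zero(self, small_plate):
        out = bscore_plate(small_plate)
        assert np.median(out.valid_values) == pytest.approx(0.0, abs=1e-6)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_to_row_offset(self, seed):
        # rows are swept first, so a constant added to a whole row is
        # absorbed into the row effect in the very first sweep and the
        # B-scores are unchanged (column offsets are only absorbed
        # approximately: they can alter the row-median trajectory)
        rng = np.random.default_rng(seed)
        base = PlateGrid(rng.standard_normal((6, 8)))
        shifted = base.copy()
        shifted.values[2, :] += 5.0
        np.testing.assert_allclose(
            bscore_plate(base, tol=1e-10).values,
            bscore_plate(shifted, tol=1e-10).values,
            atol=1e-7,
        )

    def test_column_offset_absorbed_into_column_effect(self, rng):
        # a large constant column offset ends up (mostly) in the fitted
        # column effect, not in the residuals the B-score is built from
        base = PlateGrid(rng.standard_normal((6, 8)))
        shifted = base.copy()
        shifted.values[:, 4] += 50.0
        res = median_polish(shifted, tol=1e-10)
        r0 = median_polish(base, tol=1e-10)
        assert res.col_effects[4] - r0.col_effects[4] == pytest.approx(
            50.0, abs=2.0
        )


class TestWellCorrection:
    def test_pure_trend_series_is_degenerate(self, rng):
        # every well follows value = plate index exactly: the linear fit
        # leaves zero residuals everywhere
        values = np.tile(
            np.arange(1.0, 6.0)[:, None, None], (1, 2, 3)
        )
        with pytest.raises(DegenerateDataError):
            well_correction(assay_from_array(values))

    def test_output_mean_sd_slope(self, rng):
        assay = assay_from_array(rng.standard_normal((30, 3, 4)))
        out = well_correction(assay)
        v = out.values3d()
        x = np.arange(1, 31, dtype=float)
        for i in range(3):
            for j in range(4):
                series = v[:, i, j]
                assert series.mean() == pytest.approx(0.0, abs=1e-9)
                assert series.std(ddof=1) == pytest.approx(1.0, abs=1e-9)
                slope = np.polyfit(x, series, 1)[0]
                assert slope == pytest.approx(0.0, abs=1e-9)

    def test_per_location_independence(self, rng):
        values = rng.standard_normal((10, 3, 4))
        a1 = assay_from_array(values)
        perturbed = values.copy()
        perturbed[:, 0, 0] += rng.standard_normal(10)
        a2 = assay_from_array(perturbed)
        o1, o2 = well_correction(a1), well_correction(a2)
        np.testing.assert_array_equal(
            o1.values3d()[:, 1:, :], o2.values3d()[:, 1:, :]
        )

    def test_needs_three_plates(self, rng):
        with pytest.raises(Exception):
            well_correction(assay_from_array(rng.standard_normal((2, 3, 4))))
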