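"""Detection tests: pooled t, chi-square, DFT spectrum and K-S statistic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from htsqc import (
    HitSurface,
    PlateGrid,
    UndefinedStatisticError,
    assay_from_array,
    chi2_line,
    chi2_surface,
    dft_power_spectrum,
    ks_statistic,
    ks_test_plate,
    scan_assay_ttest,
    t_test_line,
)


def naive_dft_powers(seq):
    """Brute-force O(N^2) discrete Fourier transform power spectrum."""
    n = len(seq)
    powers = []
    for k in range(1, n):
        coeff = sum(
            seq[m] * np.exp(-2j * np.pi * k * m / n) for m in range(n)
        )
        powers.append(abs(coeff) ** 2)
    return np.array(powers)


class TestTTest:
    def test_hand_example(self):
        # row {1,2,3} vs remainder {4,5,6}: pooled variance 1, t = -3.674, df 4
        p = PlateGrid(np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]))
        res = t_test_line(p, "row", 1, alpha=0.05)
        assert res.statistic == pytest.approx(-3.6742346141747673, abs=1e-12)
        assert res.p_value == pytest.approx(
            2 * stats.t.sf(3.6742346141747673, 4), abs=1e-12
        )

    def test_equal_means_not_flagged(self):
        v = np.tile(np.array([1.0, 2.0, 3.0, 4.0]), (4, 1))
        res = t_test_line(PlateGrid(v), "row", 1, alpha=0.05)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert not res.flagged

    def test_strong_shift_flagged(self, rng):
        v = rng.standard_normal((8, 12))
        v[3, :] += 10.0
        res = t_test_line(PlateGrid(v), "row", 4, alpha=0.01)
        assert res.flagged and res.p_value < 1e-6

    def test_matches_scipy_on_random_splits(self, rng):
        # oracle: scipy's pooled-variance two-sample t-test
        for _ in range(1000):
            v = rng.standard_normal((6, 9))
            kind = "row" if rng.random() < 0.5 else "col"
            index = int(rng.integers(1, 7 if kind == "row" else 10))
            res = t_test_line(PlateGrid(v), kind, index)
            sel = v[index - 1, :] if kind == "row" else v[:, index - 1]
            rest = np.delete(v, index - 1, axis=0 if kind == "row" else 1).ravel()
            ref = stats.ttest_ind(sel, rest, equal_var=True)
            assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_location_scale_invariance(self, small_plate):
        base = t_test_line(small_plate, "col", 5)
        shifted = small_plate.with_values(small_plate.values * 3.5 + 100.0)
        res = t_test_line(shifted, "col", 5)
        assert res.statistic == pytest.approx(base.statistic, abs=1e-9)

    def test_insufficient_wells_error(self):
        mask = np.ones((3, 4), dtype=bool)
        mask[0, 1:] = False
        with pytest.raises(UndefinedStatisticError):
            t_test_line(PlateGrid(np.ones((3, 4)), mask), "row", 1)

    def test_scan_shape_and_agreement_with_single_line(self, small_assay):
        results = scan_assay_ttest(small_assay, alpha=0.05)
        assert len(results) == 5 * (8 + 12)
        res = results[3]  # plate 1, row 4
        single = t_test_line(small_assay.plates[0], "row", 4, alpha=0.05)
        assert res.statistic == pytest.approx(single.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(single.p_value, abs=1e-12)

    def test_scan_handles_undefined_lines_nonfatally(self, rng):
        mask = np.ones((3, 4), dtype=bool)
        mask[0, 1:] = False
        assay = assay_from_array(rng.standard_normal((1, 3, 4)), mask[None])
        results = scan_assay_ttest(assay)
        bad = [r for r in results if not r.ok]
        assert len(bad) == 1 and bad[0].kind == "row" and not bad[0].flagged


def surface_from_counts(counts):
    counts = np.asarray(counts, dtype=int)
    return HitSurface(
        counts=counts,
        mask=np.ones(counts.shape, dtype=bool),
        threshold_c=3.0,
        scope="plate_wise",
    )


class TestChi2:
    def test_uniform_surface_statistic_zero(self):
        s = surface_from_counts(np.full((3, 4), 2))
        assert chi2_surface(s).statistic == 0.0
        assert chi2_line(s, "row", 1).statistic == 0.0
        assert chi2_surface(s).p_value == pytest.approx(1.0)

    def test_row_hand_example(self):
        # total 12 over 6 cells -> E = 2; row {1,2,3} -> ((1)+(0)+(1))/2 = 1
        s = surface_from_counts([[1, 2, 3], [2, 2, 2]])
        res = chi2_line(s, "row", 1)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(stats.chi2.sf(1.0, 2), abs=1e-12)

    def test_surface_hand_example(self):
        s = surface_from_counts([[4, 0], [0, 4]])
        res = chi2_surface(s)
        assert res.statistic == pytest.approx(8.0)
        assert res.p_value == pytest.approx(stats.chi2.sf(8.0, 3), abs=1e-12)

    def test_no_hits_is_error(self):
        s = surface_from_counts(np.zeros((2, 2)))
        with pytest.raises(UndefinedStatisticError):
            chi2_surface(s)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 9, size=(4, 6))
        counts[0, 0] += 1  # guarantee E > 0
        s = surface_from_counts(counts)
        E = counts.sum() / counts.size
        # independent brute force: sum of (obs - exp)^2 / exp cell by cell
        brute_surface = sum(
            (counts[i, j] - E) ** 2 / E
            for i in range(4)
            for j in range(6)
        )
        assert chi2_surface(s).statistic == pytest.approx(brute_surface, rel=1e-12)
        for i in range(1, 5):
            brute_row = sum((counts[i - 1, j] - E) ** 2 / E for j in range(6))
            assert chi2_line(s, "row", i).statistic == pytest.approx(brute_row, rel=1e-12)
        for j in range(1, 7):
            brute_col = sum((counts[i, j - 1] - E) ** 2 / E for i in range(4))
            assert chi2_line(s, "col", j).statistic == pytest.approx(brute_col, rel=1e-12)


class TestSpectrum:
    def test_constant_sequence_all_zero(self):
        sp = dft_power_spectrum(PlateGrid(np.full((2, 4), 3.0)), "row_major")
        np.testing.assert_allclose(sp.powers, 0.0, atol=1e-18)

    def test_alternating_sequence_energy_at_nyquist(self):
        # +1/-1 over n=16: all power at k = n/2, value n^2
        v = np.resize([1.0, -1.0], (4, 4))
        sp = dft_power_spectrum(PlateGrid(v), "row_major")
        assert sp.powers[16 // 2 - 1] == pytest.approx(16.0**2)
        others = np.delete(sp.powers, 16 // 2 - 1)
        np.testing.assert_allclose(others, 0.0, atol=1e-18)

    def test_matches_naive_dft(self, rng):
        v = rng.standard_normal((5, 7))
        mask = np.ones((5, 7), dtype=bool)
        mask[2, 3] = False  # masked wells are skipped, not imputed
        for order in ("row_major", "column_major"):
            sp = dft_power_spectrum(PlateGrid(v, mask), order)
            seq = (v if order == "row_major" else v.T).ravel()
            mseq = (mask if order == "row_major" else mask.T).ravel()
            np.testing.assert_allclose(
                sp.powers, naive_dft_powers(seq[mseq]), atol=1e-9
            )

    def test_too_few_wells(self):
        mask = np.zeros((2, 2), dtype=bool)
        mask[0, :] = True
        with pytest.raises(UndefinedStatisticError):
            dft_power_spectrum(PlateGrid(np.ones((2, 2)), mask))


class TestKS:
    def test_ascending_distinct_attains_lower_bound(self):
        # for a sequence already in rank order, position and rank agree and
        # the discrepancy is forced to its 1/N minimum
        for n in (4, 10, 95):
            d = ks_statistic(np.linspace(0.0, 1.0, n))
            assert d == pytest.approx(1.0 / n, abs=1e-12)

    def test_all_equal_values(self):
        assert ks_statistic(np.ones(4)) == pytest.approx(1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 60))
    def test_d_bounds(self, seed, n):
        powers = np.random.default_rng(seed).random(n)
        d = ks_statistic(powers)
        assert 1.0 / n - 1e-12 <= d <= 1.0

    def test_strong_column_offset_detected(self):
        # row-major order exposes column-periodic structure
        rng = np.random.default_rng(0)
        flags = []
        for _ in range(200):
            v = rng.standard_normal((8, 12))
            v[:, 4] += 3.0
            res = ks_test_plate(PlateGrid(v), alpha=0.01, orders=("row_major",))
            assert res[0].kind == "col"
            flags.append(res[0].flagged)
        assert np.mean(flags) >= 0.9

    def test_null_plates_over_reject(self):
        # the spectral rank statistic is anti-conservative on null data:
        # the mirror symmetry of real-signal spectra breaks the uniform-rank
        # assumption, so rejections exceed the nominal level
        rng = np.random.default_rng(1)
        flags = [
            ks_test_plate(PlateGrid(rng.standard_normal((8, 12))), 0.01)[0].flagged
            for _ in range(100)
        ]
        assert np.mean(flags) > 0.01

    def test_alpha_zero_never_flags(self, small_plate):
        assert not any(r.flagged for r in ks_test_plate(small_plate, alpha=0.0))
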