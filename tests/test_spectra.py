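"""Peak picking, internal calibration, nonuniform-bin alignment."""

import numpy as np
import pandas as pd
import pytest

from organellems import fixtures, spectra
from organellems.fixtures import FixtureConfig
from organellems.spectra import PeakList, PeakMatrix, align_bins, calibrate, pick_peaks


def _gaussian_spectrum(peaks, lo=490.0, hi=520.0, step=0.01, sigma=0.04, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    mz = np.arange(lo, hi, step)
    inten = np.zeros_like(mz)
    for m, h in peaks:
        inten += h * np.exp(-((mz - m) ** 2) / (2 * sigma**2))
    if noise:
        inten += rng.normal(0, noise, size=mz.shape) + 10 * noise
        np.clip(inten, 0, None, out=inten)
    return mz, inten


def _peaklist(mz_int_pairs, sid="s"):
    df = pd.DataFrame(mz_int_pairs, columns=["mz", "intensity"])
    df["snr"] = 100.0
    return PeakList(spectrum_id=sid, peaks=df, base_peak_intensity=df["intensity"].max())


class TestPickPeaks:
    def test_noise_free_peak_at_true_position_and_height(self):
        mz, inten = _gaussian_spectrum([(500.123, 80.0)])
        pl = pick_peaks(mz, inten)
        assert len(pl) == 1
        assert pl.mz[0] == pytest.approx(500.123, abs=1e-4)
        assert pl.intensity[0] == pytest.approx(80.0, rel=1e-3)

    def test_all_zero_spectrum_gives_empty_list(self):
        pl = pick_peaks(np.arange(100.0, 110.0, 0.01), np.zeros(1000))
        assert len(pl) == 0

    def test_snr_rule_agrees_with_independent_oracle(self):
        # same window definition recomputed naively, decision-by-decision
        rng = np.random.default_rng(42)
        mz = np.arange(500.0, 540.0, 0.01)
        inten = rng.normal(0, 10.0, size=mz.shape) + 100.0
        for center, h in [(505.0, 45.0), (515.0, 75.0), (525.0, 200.0)]:
            inten += h * np.exp(-((mz - center) ** 2) / (2 * 0.04**2))
        inten = np.clip(inten, 0, None)
        pl = pick_peaks(mz, inten, snr_min=5.0, rel_int_min=0.0)

        from scipy.signal import find_peaks

        # naive re-implementation of the same noise-window definition:
        # running median and running MAD over 101 points, symmetric edges
        n = len(inten)
        padded = np.pad(inten, 50, mode="symmetric")
        med = np.array([np.median(padded[i : i + 101]) for i in range(n)])
        dev = np.abs(inten - med)
        dev_p = np.pad(dev, 50, mode="symmetric")
        sigma = 1.4826 * np.array(
            [np.median(dev_p[i : i + 101]) for i in range(n)]
        )
        cand, _ = find_peaks(inten)
        expected = [
            i for i in cand if sigma[i] > 0 and (inten[i] - med[i]) / sigma[i] >= 5.0
        ]
        # decision-by-decision agreement with the oracle
        assert len(pl) == len(expected)
        for i in expected:
            assert np.min(np.abs(pl.mz - mz[i])) < 0.02

    def test_relative_intensity_threshold_is_strict_greater(self):
        # base peak 1e6 -> cutoff 100: 99 rejected, 101 retained
        mz, inten = _gaussian_spectrum(
            [(500.0, 1e6), (505.0, 99.0), (510.0, 101.0)], lo=495, hi=515
        )
        pl = pick_peaks(mz, inten, snr_min=0.0, rel_int_min=0.0001)
        found = np.sort(np.round(pl.mz, 3))
        assert 505.0 not in found
        assert np.any(np.abs(found - 510.0) < 0.01)
        assert np.any(np.abs(found - 500.0) < 0.01)

    def test_unsorted_mz_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            pick_peaks(np.array([2.0, 1.0]), np.array([0.0, 1.0]))


class TestCalibrate:
    def test_zero_drift_gives_identity_coefficients(self, calibrants):
        pl = _peaklist([(1221.6878, 500.0), (1396.7225, 400.0)])
        model, out = calibrate(pl, calibrants)
        assert model.a == pytest.approx(1.0, abs=1e-9)
        assert model.b == pytest.approx(0.0, abs=1e-9)
        assert out.calibrated

    def test_planted_drift_removed_on_truth_peaks(self, calibrants):
        cfg = FixtureConfig(seed=21, n_spectra_per_class=10, drift_ppm_range=(5.0, 5.0))
        worst = 0.0
        for spec in fixtures.make_spectra(cfg):
            if spec.class_label != "DCV":
                continue
            pl = pick_peaks(spec.mz, spec.intensity, spec.spectrum_id)
            _, out = calibrate(pl, calibrants)
            truth = np.array([t[0] for t in spec.truth_peaks])
            j = np.abs(out.mz[:, None] - truth[None, :]).argmin(axis=0)
            worst = max(worst, np.abs((out.mz[j] - truth) / truth * 1e6).max())
        assert worst <= 0.5

    def test_calibration_reduces_mean_abs_ppm(self, calibrants):
        cfg = FixtureConfig(seed=22, n_spectra_per_class=4, drift_ppm_range=(-5.0, 5.0))
        spec = next(s for s in fixtures.make_spectra(cfg) if s.class_label == "DCV")
        pl = pick_peaks(spec.mz, spec.intensity, spec.spectrum_id)
        _, out = calibrate(pl, calibrants)
        truth = np.array([t[0] for t in spec.truth_peaks])

        def mean_ppm(mzs):
            j = np.abs(mzs[:, None] - truth[None, :]).argmin(axis=0)
            return np.abs((mzs[j] - truth) / truth * 1e6).mean()

        assert mean_ppm(out.mz) < mean_ppm(pl.mz)

    def test_absent_calibrant_named_in_model(self, calibrants):
        pl = _peaklist([(1221.6878, 500.0)])  # calB missing
        model, out = calibrate(pl, calibrants)
        assert model.unmatched == ["calB"]
        assert model.n_matched == 1
        assert out.calibrated

    def test_no_matches_skips_calibration_with_warning(self, calibrants):
        pl = _peaklist([(700.0, 100.0)])
        with pytest.warns(UserWarning, match="calibration skipped"):
            model, out = calibrate(pl, calibrants)
        assert not out.calibrated
        assert model.n_matched == 0
        np.testing.assert_array_equal(out.mz, pl.mz)


class TestAlignBins:
    def test_peaks_two_ppm_apart_merge(self):
        pls = [_peaklist([(500.000, 10.0)], "a"), _peaklist([(500.001, 20.0)], "b")]
        pm = align_bins(pls, gap_ppm=5.0)
        assert pm.shape == (2, 1)

    def test_peaks_twenty_ppm_apart_split(self):
        pls = [_peaklist([(500.000, 10.0)], "a"), _peaklist([(500.010, 20.0)], "b")]
        pm = align_bins(pls, gap_ppm=5.0)
        assert pm.shape == (2, 2)

    def test_window_bounds_exclude_outside_features(self):
        pls = [_peaklist([(499.9, 5.0), (700.0, 9.0), (1100.5, 7.0)], "a")]
        pm = align_bins(pls, mz_window=(500.0, 1100.0))
        assert pm.shape == (1, 1)
        assert pm.feature_mz[0] == pytest.approx(700.0)

    def test_row_permutation_leaves_features_unchanged(self, peak_matrix, spectra_fix):
        _, specs = spectra_fix
        pls = [pick_peaks(s.mz, s.intensity, s.spectrum_id) for s in specs]
        pm_rev = align_bins(pls[::-1], gap_ppm=5.0, mz_window=(450.0, 1450.0))
        np.testing.assert_allclose(pm_rev.feature_mz, peak_matrix.feature_mz)
        order = [pm_rev.spectrum_ids.index(sid) for sid in peak_matrix.spectrum_ids]
        np.testing.assert_allclose(pm_rev.values[order], peak_matrix.values)

    def test_peak_conservation_into_nonzero_cells(self):
        pls = [
            _peaklist([(500.0, 1.0), (600.0, 2.0)], "a"),
            _peaklist([(550.0, 3.0)], "b"),
            _peaklist([(600.0005, 4.0), (650.0, 5.0)], "c"),
        ]
        pm = align_bins(pls, gap_ppm=5.0)
        assert (pm.values > 0).sum() == 5

    def test_empty_pool_gives_empty_matrix(self):
        pm = align_bins([_peaklist([], "a")])
        assert pm.shape == (1, 0)

    def test_representative_mz_is_weighted_mean(self):
        pls = [_peaklist([(500.000, 10.0)], "a"), _peaklist([(500.001, 30.0)], "b")]
        pm = align_bins(pls)
        expected = (500.000 * 10 + 500.001 * 30) / 40
        assert pm.feature_mz[0] == pytest.approx(expected, abs=1e-9)

    def test_csv_round_trip(self, tmp_path):
        pls = [_peaklist([(500.0, 1.5), (600.0, 2.5)], "a"), _peaklist([(600.0, 4.0)], "b")]
        pm = align_bins(pls)
        path = tmp_path / "pm.csv"
        pm.to_csv(path)
        back = PeakMatrix.from_csv(path)
        np.testing.assert_allclose(back.values, pm.values)
        np.testing.assert_allclose(back.feature_mz, pm.feature_mz, atol=1e-6)
        assert back.spectrum_ids == pm.spectrum_ids
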