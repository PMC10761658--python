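"""Spectral-image I/O, energy windowing, uniformity and ROI count rates."""

import numpy as np
import pytest

from luquant.errors import (FormatError, NoPixelsError, NoSignalError,
                            ValidationError)
from luquant.spectra import (EnergyWindow, Roi, SpectralImage,
                             apply_uniformity, auto_roi, extract_window_image,
                             read_spectral_image, roi_count_rate,
                             write_spectral_image)


def make_image(counts, duration=100.0):
    return SpectralImage(counts=counts, duration_s=duration, collimator="MEGP")


def random_image(rng, lam=0.05, duration=100.0):
    return make_image(rng.poisson(lam, size=(16, 16, 2500)), duration)


class TestIO:
    @pytest.mark.parametrize("suffix", [".h5", ".csv"])
    def test_roundtrip_bit_identical(self, rng, tmp_path, suffix):
        img = random_image(rng)
        path = tmp_path / f"img{suffix}"
        write_spectral_image(img, path)
        back = read_spectral_image(path)
        np.testing.assert_array_equal(back.counts, img.counts)
        assert back.duration_s == img.duration_s
        assert back.collimator == img.collimator

    def test_single_count_identity(self, tmp_path):
        counts = np.zeros((16, 16, 2500), dtype=np.uint32)
        counts[0, 0, 1130] = 1   # one count in the bin [113.0, 113.1) keV
        img = make_image(counts)
        path = tmp_path / "one.h5"
        write_spectral_image(img, path)
        assert read_spectral_image(path).total_counts == 1

    def test_malformed_shape_rejected(self):
        with pytest.raises(FormatError):
            make_image(np.zeros((16, 16, 100), dtype=int))

    def test_negative_counts_rejected(self):
        counts = np.zeros((16, 16, 2500), dtype=np.int64)
        counts[3, 3, 3] = -1
        with pytest.raises(ValidationError):
            make_image(counts)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FormatError):
            read_spectral_image(tmp_path / "absent.h5")

    def test_energy_shift_moves_counts_between_windows(self):
        counts = np.zeros((16, 16, 2500), dtype=np.uint32)
        counts[5, 5, 1207] = 7   # [120.7, 120.8): last bin of the 113 main window
        img = make_image(counts).energy_shifted(1)
        w_main = EnergyWindow("m", 100.5, 120.8)
        w_upper = EnergyWindow("u", 120.8, 124.8)
        assert extract_window_image(img, w_main).total == 0
        assert extract_window_image(img, w_upper).total == 7


class TestWindowExtraction:
    def test_in_window_bin_retained(self, windows):
        counts = np.zeros((16, 16, 2500), dtype=np.uint32)
        counts[:, :, 1130] = 3   # [113.0, 113.1) keV
        wi = extract_window_image(make_image(counts), windows[113].main)
        assert wi.total == 3 * 256

    def test_upper_edge_bin_excluded(self, windows):
        # a count at [120.8, 120.9) belongs to the upper scatter window
        counts = np.zeros((16, 16, 2500), dtype=np.uint32)
        counts[:, :, 1208] = 2
        assert extract_window_image(make_image(counts), windows[113].main).total == 0
        assert extract_window_image(
            make_image(counts), windows[113].upper_scatter).total == 2 * 256

    def test_matches_bruteforce_loop(self, rng, windows):
        img = random_image(rng, lam=0.2)
        for pk in windows.values():
            for w in (pk.lower_scatter, pk.main, pk.upper_scatter):
                wi = extract_window_image(img, w)
                expected = np.zeros((16, 16))
                for b in range(2500):
                    if 0.1 * b >= w.lo - 1e-9 and 0.1 * (b + 1) <= w.hi + 1e-9:
                        expected += img.counts[:, :, b]
                np.testing.assert_allclose(wi.values, expected)

    def test_abutting_windows_conserve_counts(self, rng, windows):
        img = random_image(rng, lam=0.2)
        for pk in windows.values():
            total = sum(extract_window_image(img, w).total
                        for w in (pk.lower_scatter, pk.main, pk.upper_scatter))
            enclosing = EnergyWindow("enc", pk.lower_scatter.lo, pk.upper_scatter.hi)
            assert total == extract_window_image(img, enclosing).total

    def test_off_grid_window_rejected(self):
        with pytest.raises(ValidationError):
            EnergyWindow("bad", 100.55, 120.8)


class TestUniformity:
    def test_identity_and_linearity(self, rng, windows):
        img = random_image(rng)
        wi = extract_window_image(img, windows[113].main)
        same = apply_uniformity(wi, np.ones((16, 16)))
        np.testing.assert_array_equal(same.values, wi.values)
        doubled = apply_uniformity(wi, 2.0 * np.ones((16, 16)))
        assert doubled.total == pytest.approx(2 * wi.total)

    def test_elementwise_product(self, rng, windows):
        img = random_image(rng)
        wi = extract_window_image(img, windows[113].main)
        corr = rng.uniform(0.8, 1.2, size=(16, 16))
        out = apply_uniformity(wi, corr)
        np.testing.assert_allclose(out.values, wi.values * corr)
        np.testing.assert_allclose(out.variance, wi.variance * corr ** 2)

    def test_commutes_with_extraction_for_constant_correction(self, rng, windows):
        img = random_image(rng)
        corr = 1.37 * np.ones((16, 16))
        a = apply_uniformity(extract_window_image(img, windows[55].main), corr)
        summed = (img.counts[:, :, windows[55].main.bin_slice] * 1.37).sum(axis=2)
        np.testing.assert_allclose(a.values, summed)

    def test_nonpositive_correction_rejected(self, rng, windows):
        wi = extract_window_image(random_image(rng), windows[113].main)
        with pytest.raises(ValidationError):
            apply_uniformity(wi, np.zeros((16, 16)))


class TestAutoRoi:
    def test_single_hot_pixel(self, windows):
        counts = np.zeros((16, 16, 2500), dtype=np.uint32)
        counts[8, 8, 1130] = 100
        wi = extract_window_image(make_image(counts), windows[113].main)
        roi = auto_roi(wi, source_radius_mm=10.0, fwhm_mm=8.0)
        assert roi.center == (8.0, 8.0)
        assert roi.radius_mm == 14.0

    def test_symmetric_pair_centers_between(self, windows):
        counts = np.zeros((16, 16, 2500), dtype=np.uint32)
        counts[4, 8, 1130] = 50
        counts[12, 8, 1130] = 50
        wi = extract_window_image(make_image(counts), windows[113].main)
        assert auto_roi(wi, 10, 8).center == (8.0, 8.0)

    def test_center_is_count_weighted_com(self, rng, windows):
        img = random_image(rng, lam=0.5)
        wi = extract_window_image(img, windows[113].main)
        roi = auto_roi(wi, 10, 8)
        rr, cc = np.mgrid[0:16, 0:16]
        assert roi.center[0] == pytest.approx((rr * wi.values).sum() / wi.values.sum())
        assert roi.center[1] == pytest.approx((cc * wi.values).sum() / wi.values.sum())

    def test_translation_equivariance(self, windows):
        rng = np.random.default_rng(7)
        blob = rng.poisson(5.0, size=(5, 5))
        base = np.zeros((16, 16, 2500), dtype=np.int64)
        base[3:8, 3:8, 1130] = blob
        shifted = np.zeros_like(base)
        shifted[6:11, 5:10, 1130] = blob
        r1 = auto_roi(extract_window_image(make_image(base), windows[113].main), 10, 8)
        r2 = auto_roi(extract_window_image(make_image(shifted), windows[113].main), 10, 8)
        assert r2.center[0] - r1.center[0] == pytest.approx(3.0)
        assert r2.center[1] - r1.center[1] == pytest.approx(2.0)

    def test_all_zero_image_raises(self, windows):
        wi = extract_window_image(
            make_image(np.zeros((16, 16, 2500), dtype=np.uint32)), windows[113].main)
        with pytest.raises(NoSignalError):
            auto_roi(wi, 10, 8)


class TestRoiCountRate:
    def test_full_detector_rate_and_variance(self, windows):
        counts = np.zeros((16, 16, 2500), dtype=np.uint32)
        counts[2:7, 3:8, 1100] = 40   # 25 pixels x 40 = 1000 counts
        wi = extract_window_image(make_image(counts, duration=100.0), windows[113].main)
        roi = Roi.from_mask(np.ones((16, 16), dtype=bool))
        out = roi_count_rate(wi, roi)
        assert out["rate"] == pytest.approx(10.0)
        assert out["variance"] == pytest.approx(0.1)

    def test_roi_excluding_all_counts_gives_zero(self, windows):
        counts = np.zeros((16, 16, 2500), dtype=np.uint32)
        counts[0, 0, 1130] = 40
        wi = extract_window_image(make_image(counts), windows[113].main)
        out = roi_count_rate(wi, Roi.circle((15.0, 15.0), 3.0))
        assert out["rate"] == 0.0

    def test_matches_bruteforce_membership(self, rng, windows):
        img = random_image(rng, lam=0.3)
        wi = extract_window_image(img, windows[113].main)
        for _ in range(20):
            center = tuple(rng.uniform(0, 15, size=2))
            radius = float(rng.uniform(3, 25))
            roi = Roi.circle(center, radius)
            total = 0.0
            for r in range(16):
                for c in range(16):
                    dist = 2.46 * np.hypot(r - center[0], c - center[1])
                    if dist <= radius:
                        total += wi.values[r, c]
            out = roi_count_rate(wi, roi)
            assert out["rate"] == pytest.approx(total / wi.duration_s)

    def test_full_mask_times_duration_is_total(self, rng, windows):
        img = random_image(rng)
        wi = extract_window_image(img, windows[208].main)
        out = roi_count_rate(wi, Roi.from_mask(np.ones((16, 16), dtype=bool)))
        assert out["rate"] * wi.duration_s == pytest.approx(wi.total)

    def test_offgrid_circle_raises(self, rng, windows):
        wi = extract_window_image(random_image(rng), windows[113].main)
        with pytest.raises(NoPixelsError):
            roi_count_rate(wi, Roi.circle((40.0, 40.0), 2.0))


class TestYamlRoundtrips:
    def test_window_set(self, tmp_path, windows):
        from luquant.spectra import EnergyWindowSet
        p = tmp_path / "w.yaml"
        windows.to_yaml(p)
        back = EnergyWindowSet.from_yaml(p)
        assert back[113].main.lo == 100.5 and back[113].main.hi == 120.8
        assert back.labels == windows.labels

    @pytest.mark.parametrize("roi", [
        Roi.circle((7.5, 8.25), 12.0),
        Roi.from_mask(np.eye(16, dtype=bool)),
    ])
    def test_roi(self, tmp_path, roi):
        p = tmp_path / "roi.yaml"
        roi.to_yaml(p)
        back = Roi.from_yaml(p)
        np.testing.assert_array_equal(back.membership(), roi.membership())
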