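"""Spot detection, 2D-Gaussian fitting and density counting."""

import math

import numpy as np
import pytest

from tgtquant import spots
from tgtquant.simulate import ImageFrame, OpticsModel, simulate_molecule_field
from tgtquant.simulate import _render_spots
from tgtquant.spots import (
    DetectionParams,
    count_spots,
    detect_candidates,
    fit_gaussian_2d,
    quantify_clusters,
)


def _gaussian_frame(x0, y0, a, sigma, b, shape=(31, 31), pixel_size=0.16):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    data = b + a * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma**2))
    return ImageFrame(data, pixel_size)


def _spot_field(positions_px, photons, shape=(128, 128), offset=100.0, noise=None, seed=0):
    """Render known spots with optional Poisson+read noise."""
    x = np.array([p[1] for p in positions_px], dtype=float)
    y = np.array([p[0] for p in positions_px], dtype=float)
    signal = _render_spots(shape, x, y, np.asarray(photons, dtype=float), sigma_px=0.94)
    if noise is None:
        data = signal + offset
    else:
        rng = np.random.default_rng(seed)
        data = rng.poisson(signal).astype(float) + offset + rng.normal(0, noise, shape)
    return ImageFrame(data, 0.16)


class TestDetect:
    def test_constant_image_yields_no_candidates(self):
        frame = ImageFrame(np.full((64, 64), 50.0), 0.16)
        assert detect_candidates(frame).size == 0

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            detect_candidates(ImageFrame(np.empty((0, 0)), 0.16))

    def test_grid_of_bright_spots_recovered_with_no_false_positives(self):
        # 50 well-separated spots; photon budget gives SNR ~ 10
        rng = np.random.default_rng(42)
        rows = np.arange(10, 128, 17)
        cols = np.arange(12, 128, 18)
        positions = [(r, c) for r in rows[:8] for c in cols[:7]][:50]
        jitter = rng.uniform(-1, 1, (len(positions), 2))
        positions = [(r + dr, c + dc) for (r, c), (dr, dc) in zip(positions, jitter)]
        frame = _spot_field(positions, [800] * len(positions), noise=2.0, seed=1)
        coords = detect_candidates(frame)
        # match detections to truth within 3 px
        truth = np.array(positions)
        found = 0
        for t in truth:
            if np.min(np.hypot(*(coords - t).T)) < 3:
                found += 1
        assert found >= 49
        assert len(coords) <= len(positions) + 1

    def test_detection_is_deterministic(self):
        frame = _spot_field([(30, 30), (60, 80)], [800, 900], noise=2.0, seed=5)
        a = detect_candidates(frame)
        b = detect_candidates(frame)
        assert np.array_equal(a, b)

    def test_offset_invariance(self):
        frame = _spot_field([(30, 30), (60, 80)], [800, 900], noise=2.0, seed=5)
        shifted = ImageFrame(frame.data + 500.0, frame.pixel_size)
        assert np.array_equal(detect_candidates(frame), detect_candidates(shifted))


class TestFit:
    def test_noiseless_gaussian_recovered_exactly(self):
        frame = _gaussian_frame(15.3, 14.7, 1000.0, 2.0, 100.0)
        fit = fit_gaussian_2d(frame, (15, 15), DetectionParams(fit_halfwidth=8))
        assert fit.converged
        assert fit.x0 == pytest.approx(15.3, rel=1e-6)
        assert fit.y0 == pytest.approx(14.7, rel=1e-6)
        assert fit.amplitude == pytest.approx(1000.0, rel=1e-6)
        assert fit.sigma == pytest.approx(2.0, rel=1e-6)
        assert fit.background == pytest.approx(100.0, rel=1e-6)

    def test_integrated_intensity_matches_pixel_sum(self):
        # discrete sum of the rendered Gaussian vs the analytic 2*pi*A*sigma^2
        frame = _gaussian_frame(15.0, 15.0, 500.0, 1.8, 0.0)
        fit = fit_gaussian_2d(frame, (15, 15), DetectionParams(fit_halfwidth=10))
        assert fit.integrated_intensity == pytest.approx(float(frame.data.sum()), rel=0.005)

    def test_border_window_flagged_not_fitted(self):
        frame = _gaussian_frame(2.0, 2.0, 500.0, 1.5, 10.0)
        fit = fit_gaussian_2d(frame, (2, 2), DetectionParams(fit_halfwidth=5))
        assert not fit.converged
        assert "border" in fit.flags

    def test_translation_equivariance_whole_pixels(self):
        params = DetectionParams(fit_halfwidth=6)
        base = _gaussian_frame(12.4, 13.6, 800.0, 1.5, 50.0, shape=(40, 40))
        shifted = ImageFrame(np.roll(np.roll(base.data, 5, axis=0), 7, axis=1), 0.16)
        f0 = fit_gaussian_2d(base, (14, 12), params)
        f1 = fit_gaussian_2d(shifted, (19, 19), params)
        assert f1.x0 - f0.x0 == pytest.approx(7.0, abs=1e-6)
        assert f1.y0 - f0.y0 == pytest.approx(5.0, abs=1e-6)
        assert f1.amplitude == pytest.approx(f0.amplitude, rel=1e-6)

    def test_integrated_intensity_unbiased_under_poisson_noise(self):
        # SNR ~ 10 spot refitted over many noise realisations; the fitted
        # photon budget (2*pi*A*sigma^2) is bias-free within 2%
        totals = []
        for seed in range(200):
            frame = _spot_field([(15.0, 15.0)], [800.0], shape=(31, 31), noise=2.0, seed=seed)
            fit = fit_gaussian_2d(frame, (15, 15))
            if fit.converged:
                totals.append(fit.integrated_intensity)
        assert len(totals) >= 195
        assert np.mean(totals) == pytest.approx(800.0, rel=0.02)


class TestCount:
    def test_empty_field_zero_density(self, small_optics):
        frame, _ = simulate_molecule_field(0.0, small_optics, seed=1)
        count, density = count_spots(frame, (8, 8, 80, 80), small_optics)
        assert count == 0 and density == 0.0

    def test_zero_area_roi_rejected(self, small_optics):
        frame, _ = simulate_molecule_field(0.0, small_optics, seed=1)
        with pytest.raises(ValueError):
            count_spots(frame, (0, 0, 0, 10), small_optics)

    def test_count_invariant_to_offset(self, small_optics):
        frame, _ = simulate_molecule_field(0.5, small_optics, seed=6)
        shifted = ImageFrame(frame.data + 300.0, frame.pixel_size)
        roi = (8, 8, 80, 80)
        assert count_spots(frame, roi, small_optics)[0] == count_spots(
            shifted, roi, small_optics
        )[0]

    def test_low_density_recovery_pooled_over_rois(self):
        """Density 0.3/µm² (the sparsest printed surface) within 10% pooled."""
        optics = OpticsModel(frame_shape=(152, 152))
        densities = []
        for seed in range(10):
            frame, _ = simulate_molecule_field(0.3, optics, seed=300 + seed)
            _, density = count_spots(frame, (8, 8, 136, 136), optics)
            densities.append(density)
        assert np.mean(densities) == pytest.approx(0.3, rel=0.10)

    def test_counting_unbiased_across_low_density_range(self):
        """Mean relative error < 5% for 0.3-1 molecules/µm²."""
        optics = OpticsModel(frame_shape=(152, 152))
        errors = []
        for density, seed0 in [(0.3, 1000), (0.6, 2000), (1.0, 3000)]:
            est, truth_n = [], 0
            for k in range(6):
                frame, truth = simulate_molecule_field(density, optics, seed=seed0 + k)
                _, d = count_spots(frame, (8, 8, 136, 136), optics)
                est.append(d)
                pos = truth.molecule_positions / optics.pixel_size
                truth_n += (
                    (pos[:, 0] >= 8) & (pos[:, 0] < 144) & (pos[:, 1] >= 8) & (pos[:, 1] < 144)
                ).sum()
            realized = truth_n / (6 * 136 * 136 * optics.pixel_size**2)
            errors.append(np.mean(est) / realized - 1)
        assert np.mean(np.abs(errors)) < 0.05


class TestClusters:
    def test_two_clusters_fi_ratio_two(self):
        frame = _spot_field([(40, 30), (40, 90)], [3000, 6000], noise=2.0, seed=3)
        mask = np.ones(frame.data.shape, dtype=bool)
        fits = sorted((f for f in quantify_clusters(frame, mask) if f.ok), key=lambda f: f.x0)
        assert len(fits) == 2
        ratio = fits[1].integrated_intensity / fits[0].integrated_intensity
        assert ratio == pytest.approx(2.0, rel=0.02)

    def test_cluster_at_mask_border_excluded_and_reported(self):
        frame = _spot_field([(40, 30), (40, 64)], [3000, 3000], noise=2.0, seed=4)
        mask = np.zeros(frame.data.shape, dtype=bool)
        mask[:, :67] = True  # second cluster sits 3 px from the mask edge
        fits = quantify_clusters(frame, mask)
        assert len(fits) == 2
        flagged = [f for f in fits if "mask_border" in f.flags]
        kept = [f for f in fits if f.ok]
        assert len(flagged) == 1 and len(kept) == 1
        assert flagged[0].x0 == pytest.approx(64, abs=2)

    def test_fi_invariant_to_background_level(self):
        frame = _spot_field([(40, 40)], [3000], noise=None)
        lifted = ImageFrame(frame.data + 250.0, frame.pixel_size)
        mask = np.ones(frame.data.shape, dtype=bool)
        fi0 = [f for f in quantify_clusters(frame, mask) if f.ok][0].integrated_intensity
        fi1 = [f for f in quantify_clusters(lifted, mask) if f.ok][0].integrated_intensity
        assert fi1 == pytest.approx(fi0, rel=1e-3)

    def test_empty_mask_rejected(self):
        frame = _spot_field([(40, 40)], [3000])
        with pytest.raises(ValueError):
            quantify_clusters(frame, np.zeros(frame.data.shape, dtype=bool))
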