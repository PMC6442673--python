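import numpy as np
import pytest
from conftest import make_noiseless_spark_image

from casparks import (
    DetectionParams,
    ExperimentStage,
    LinescanImage,
    detect,
    find_spark_regions,
    smooth_image,
    threshold_masks,
)


class TestSmoothImage:
    def test_constant_preserved(self):
        img = np.full((10, 10), 3.5)
        assert np.allclose(smooth_image(img, 3, 3), 3.5)

    def test_single_impulse_removed_by_median(self):
        img = np.zeros((9, 9))
        img[4, 4] = 100.0
        out = smooth_image(img, 3, 1)
        assert np.all(out == 0.0)

    def test_boxcar_oracle_on_block(self):
        # 5x5 block of ones, 3x3 boxcar only: direct convolution oracle
        from scipy.signal import convolve2d

        img = np.zeros((11, 11))
        img[3:8, 3:8] = 1.0
        out = smooth_image(img, 1, 3)
        oracle = convolve2d(
            np.pad(img, 1, mode="reflect"), np.full((3, 3), 1 / 9), mode="valid"
        )
        assert np.allclose(out, oracle, atol=1e-6)
        assert out[5, 5] == pytest.approx(1.0)  # interior
        assert out[3, 5] == pytest.approx(2 / 3)  # edge ring of the block

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            smooth_image(np.zeros((5, 5)), 4, 3)

    def test_kernel_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            smooth_image(np.zeros((3, 100)), 5, 3)


class TestThresholdMasks:
    def test_subthreshold_image_gives_empty_region_mask(self, rng):
        smoothed = rng.normal(0, 1, (50, 50)) * 0.1  # everything below 2 sd
        region, peak = threshold_masks(smoothed, sd=1.0, params=DetectionParams())
        assert not region.any()

    def test_single_hot_pixel_suppressed_in_peak_mask(self):
        smoothed = np.zeros((15, 15))
        smoothed[7, 7] = 10.0
        region, peak = threshold_masks(smoothed, sd=1.0, params=DetectionParams())
        assert region[7, 7]
        assert not peak.any()  # isolated pixel: the median filter's purpose

    def test_block_at_kernel_scale_survives_peak_median(self):
        # a suprathreshold block the size of the peak-median kernel keeps
        # its centre pixel (majority of the window is above threshold)
        k = DetectionParams().peak_median_size_px
        smoothed = np.zeros((15, 15))
        smoothed[7 - k // 2 : 8 + k // 2, 7 - k // 2 : 8 + k // 2] = 10.0
        _, peak = threshold_masks(smoothed, sd=1.0, params=DetectionParams())
        assert peak[7, 7]

    def test_zero_sd_returns_empty_masks(self):
        region, peak = threshold_masks(np.ones((5, 5)), 0.0, DetectionParams())
        assert not region.any() and not peak.any()


class TestFindSparkRegions:
    def _masks(self, shape, blocks):
        region = np.zeros(shape, bool)
        for (x0, x1, t0, t1) in blocks:
            region[x0:x1, t0:t1] = True
        return region

    def test_39_pixel_region_rejected_at_min_40(self):
        region = self._masks((30, 30), [(5, 8, 5, 18)])  # 3x13 = 39 px
        peak = region.copy()
        smoothed = region.astype(float)
        assert find_spark_regions(region, peak, smoothed, 40) == []

    def test_40_pixel_region_with_peak_kept(self):
        region = self._masks((30, 30), [(5, 10, 5, 13)])  # 5x8 = 40 px
        peak = np.zeros_like(region)
        peak[7, 9] = True
        smoothed = region.astype(float)
        smoothed[7, 9] = 2.0
        regions = find_spark_regions(region, peak, smoothed, 40)
        assert len(regions) == 1
        assert regions[0].n_pixels == 40
        assert regions[0].peak_px == (7, 9)

    def test_region_without_peak_pixel_rejected(self):
        region = self._masks((30, 30), [(5, 15, 5, 15)])
        peak = np.zeros_like(region)
        assert find_spark_regions(region, peak, region.astype(float), 40) == []

    def test_two_components_labeled_disjoint(self):
        # oracle: hand-built mask with two separated blocks
        region = self._masks((40, 40), [(2, 9, 2, 9), (20, 30, 20, 30)])
        peak = self._masks((40, 40), [(4, 6, 4, 6), (24, 26, 24, 26)])
        smoothed = region.astype(float)
        smoothed[5, 5] = 3.0
        smoothed[25, 25] = 4.0
        regions = find_spark_regions(region, peak, smoothed, 40)
        assert len(regions) == 2
        pix = [set(zip(r.xs.tolist(), r.ts.tolist())) for r in regions]
        assert pix[0].isdisjoint(pix[1])
        # ordered by peak time
        assert regions[0].peak_px[1] <= regions[1].peak_px[1]

    def test_connectivity_choice(self):
        region = np.zeros((50, 50), bool)
        region[0:7, 0:7] = True
        region[7:14, 7:14] = True  # touches only diagonally at (6,6)/(7,7)
        peak = region.copy()
        smoothed = region.astype(float)
        r8 = find_spark_regions(region, peak, smoothed, 40, connectivity=8)
        r4 = find_spark_regions(region, peak, smoothed, 40, connectivity=4)
        assert len(r8) == 1
        assert len(r4) == 2


class TestDetect:
    def test_noiseless_single_spark_found_at_center(self):
        image, (cx, ct) = make_noiseless_spark_image(R=1.0, f0=100.0)
        result = detect(image)
        assert len(result.regions) == 1
        px, pt = result.regions[0].peak_px
        assert abs(px - cx) <= 1
        assert abs(pt - ct) <= 1

    def test_deterministic(self, small_synthetic_config):
        from casparks import generate_experiment

        image, _ = generate_experiment(small_synthetic_config)
        r1 = detect(image)
        r2 = detect(image)
        assert len(r1.regions) == len(r2.regions)
        assert r1.sd == r2.sd
        for a, b in zip(r1.regions, r2.regions):
            assert a.peak_px == b.peak_px
            assert np.array_equal(a.xs, b.xs)

    def test_gain_invariance(self):
        image, _ = make_noiseless_spark_image(R=0.9, f0=80.0, n_x=96, n_t=2000)
        scaled = LinescanImage(
            image.data.astype(np.uint32) * 3, image.pixel_size_um, image.line_interval_ms
        )
        r1 = detect(image)
        r2 = detect(scaled)
        assert len(r1.regions) == len(r2.regions) == 1
        assert np.array_equal(r1.regions[0].xs, r2.regions[0].xs)
        assert np.array_equal(r1.regions[0].ts, r2.regions[0].ts)

    def test_raising_thresholds_never_adds_regions(self):
        from casparks import generate_experiment, SyntheticConfig

        image, _ = generate_experiment(SyntheticConfig(n_x=128, n_t=6000, seed=13))
        stage = ExperimentStage.full(image)
        base = len(detect(image, stage, DetectionParams()).regions)
        stricter = DetectionParams(spark_intensity=2.6)
        larger = DetectionParams(min_region_px=80)
        assert len(detect(image, stage, stricter).regions) <= base
        assert len(detect(image, stage, larger).regions) <= base
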