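import numpy as np
import pandas as pd
import pytest

from casparks.detection import SparkRegion
from casparks.evaluation import (
    MatchResult,
    fp_frequency,
    match_detections,
    morphology_recovery,
    ppv_by_estimated_amplitude,
    sensitivity_by_amplitude,
)

DX, DT = 0.14, 1.53


def block_region(rid, x0, x1, t0, t1, peak=None):
    xs, ts = np.meshgrid(np.arange(x0, x1), np.arange(t0, t1), indexing="ij")
    if peak is None:
        peak = ((x0 + x1) // 2, (t0 + t1) // 2)
    return SparkRegion(rid, xs.ravel(), ts.ravel(), (x0, x1, t0, t1), peak)


def truth_frame(centers):
    return pd.DataFrame(
        {
            "x_center_um": [c[0] for c in centers],
            "t_center_ms": [c[1] for c in centers],
            "amplitude": [c[2] for c in centers],
        }
    )


class TestMatchDetections:
    def test_centers_inside_regions_all_matched(self):
        truth = truth_frame([(10 * DX, 100 * DT, 0.5), (50 * DX, 400 * DT, 1.0)])
        regions = [
            block_region(0, 5, 15, 80, 120),
            block_region(1, 45, 55, 380, 420),
        ]
        m = match_detections(truth, regions, DX, DT)
        assert m.pairs == {0: 0, 1: 1}
        assert m.false_negatives == [] and m.false_positives == []

    def test_no_detections_all_false_negative(self):
        truth = truth_frame([(1.0, 100.0, 0.5), (5.0, 500.0, 1.0)])
        m = match_detections(truth, [], DX, DT)
        assert m.pairs == {}
        assert m.false_negatives == [0, 1]

    def test_closer_of_two_regions_matched_other_is_fp(self):
        # brute-force expectation: the nearer peak wins the single truth
        cx, ct = 30, 300
        truth = truth_frame([(cx * DX, ct * DT, 1.0)])
        near = block_region(0, 25, 35, 280, 320, peak=(cx + 1, ct + 2))
        far = block_region(1, 25, 35, 330, 370, peak=(cx + 2, ct + 9))
        far.xs = far.xs[far.ts > 320]  # make sure center is not inside "far"
        m = match_detections(truth, [near, far], DX, DT)
        assert m.pairs == {0: 0}
        assert m.false_positives == [1]

    def test_distance_tolerance_respected(self):
        truth = truth_frame([(0.0, 0.0, 1.0)])
        region = block_region(0, 40, 50, 500, 520)  # far away
        m = match_detections(truth, [region], DX, DT)
        assert m.pairs == {}
        assert m.false_positives == [0]

    def test_classification_is_a_partition(self):
        rng = np.random.default_rng(0)
        truth = truth_frame(
            [(float(x), float(t), 1.0) for x, t in rng.uniform(0, 50, (20, 2)) * [1, 100]]
        )
        regions = [
            block_region(i, 3 * i, 3 * i + 8, 100 * i, 100 * i + 40) for i in range(12)
        ]
        m = match_detections(truth, regions, DX, DT)
        assert m.n_tp + len(m.false_negatives) == len(truth)
        assert m.n_tp + len(m.false_positives) == len(regions)


class TestCurves:
    def test_sensitivity_all_matched(self):
        truth = truth_frame([(1, 1, 0.5), (2, 2, 0.5), (3, 3, 1.0)])
        m = MatchResult({0: 0, 1: 1, 2: 2}, [], [])
        out = sensitivity_by_amplitude([(truth, m)])
        assert (out.sensitivity == 1.0).all()
        assert out.n_sparks.sum() == 3

    def test_sensitivity_pools_experiments(self):
        truth = truth_frame([(1, 1, 0.5)])
        hit = MatchResult({0: 0}, [], [])
        miss = MatchResult({}, [0], [])
        out = sensitivity_by_amplitude([(truth, hit), (truth, miss)])
        assert out.loc[0, "sensitivity"] == 0.5

    def test_fp_frequency_zero_without_fps(self):
        out = fp_frequency(np.array([]), np.array([0.0, 0.5, 1.0]), 71.68, 56.61)
        assert (out.fp_frequency == 0).all()

    def test_fp_frequency_monotone_nonincreasing(self):
        out = fp_frequency(
            np.array([0.2, 0.4, 0.6, 0.9]), np.linspace(0, 1, 11), 71.68, 56.61
        )
        assert (np.diff(out.fp_frequency) <= 0).all()

    def test_fp_frequency_normalization(self):
        # 1 FP in one experiment of 71.68 um x 56.61 s
        out = fp_frequency(np.array([0.5]), np.array([0.0]), 71.68, 56.61)
        assert out.fp_frequency[0] == pytest.approx(1 / (56.61 * 0.7168))

    def test_ppv_arithmetic(self):
        tp = np.full(10, 0.52)
        fp = np.full(10, 0.52)
        out = ppv_by_estimated_amplitude(tp, fp, bin_width=0.05, min_events=19)
        assert len(out) == 1
        assert out.ppv_percent[0] == pytest.approx(50.0)

    def test_ppv_no_fps_is_100(self):
        tp = np.concatenate([np.full(30, 0.42), np.full(25, 0.91)])
        out = ppv_by_estimated_amplitude(tp, np.array([]), min_events=20)
        assert (out.ppv_percent == 100.0).all()

    def test_ppv_small_bins_suppressed(self):
        out = ppv_by_estimated_amplitude(np.full(20, 0.3), np.array([]), min_events=20)
        assert len(out) == 0  # needs more than min_events


class TestMorphologyRecovery:
    def test_noiseless_condition_matches_truth(self):
        records = pd.DataFrame(
            {
                "snr": np.inf,
                "true_amplitude": 1.0,
                "amplitude": np.full(30, 1.001),
                "fdhm_ms": np.full(30, 25.0),
                "fwhm_um": np.full(30, 3.0),
            }
        )
        out = morphology_recovery(records)
        assert len(out) == 1
        assert out.mean_amplitude[0] == pytest.approx(1.0, rel=0.02)

    def test_sparse_conditions_suppressed(self):
        records = pd.DataFrame(
            {
                "snr": [2.0] * 10,
                "true_amplitude": [0.5] * 10,
                "amplitude": [0.6] * 10,
                "fdhm_ms": [20.0] * 10,
                "fwhm_um": [2.5] * 10,
            }
        )
        assert len(morphology_recovery(records, min_sparks=25)) == 0

    def test_nan_widths_ignored_in_means(self):
        records = pd.DataFrame(
            {
                "snr": [2.0] * 30,
                "true_amplitude": [1.0] * 30,
                "amplitude": [1.0] * 30,
                "fdhm_ms": [25.0] * 29 + [np.nan],
                "fwhm_um": [3.0] * 30,
            }
        )
        out = morphology_recovery(records)
        assert out.mean_fdhm_ms[0] == pytest.approx(25.0)
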