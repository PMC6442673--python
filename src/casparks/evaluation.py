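"""Detector validation against ground truth: sensitivity, FP rate, PPV.

Detections are matched one-to-one to ground-truth sparks: a truth spark is
a candidate match for a region if its centre pixel lies inside the region's
pixel set, or failing that if the region peak lies within a physical
tolerance (1 um, 20 ms by default — well inside one spark footprint) of the
centre.  Candidates are assigned greedily by increasing peak distance,
centre-inside candidates first.  Matched pairs are true positives,
unmatched truths false negatives, unmatched detections false positives.

From matched batches the module computes the standard performance curves:

* sensitivity as a function of the *true* amplitude,
* false-positive frequency in sparks/(s*100 um) above a cutoff amplitude,
* positive predictive value binned by the *estimated* amplitude,
* recovery of amplitude/FDHM/FWHM per (noise level, amplitude) condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detection import SparkRegion

__all__ = [
    "MatchResult",
    "match_detections",
    "sensitivity_by_amplitude",
    "fp_frequency",
    "ppv_by_estimated_amplitude",
    "morphology_recovery",
]


@dataclass
class MatchResult:
    """One-to-one classification of truths and detections for one image.

    ``pairs`` maps truth index -> region id.  Every truth appears either in
    ``pairs`` or in ``false_negatives``; every region either in ``pairs``
    or in ``false_positives``.
    """

    pairs: dict[int, int]
    false_negatives: list[int]
    false_positives: list[int]

    @property
    def n_tp(self) -> int:
        return len(self.pairs)


def match_detections(
    truth: pd.DataFrame,
    regions: list[SparkRegion],
    pixel_size_um: float,
    line_interval_ms: float,
    max_dx_um: float = 1.0,
    max_dt_ms: float = 20.0,
) -> MatchResult:
    """Greedy one-to-one matching of ground truth to detected regions.

    ``truth`` needs columns ``x_center_um``, ``t_center_ms`` (stage
    coordinates) and its positional index identifies each spark.
    """
    n_truth = len(truth)
    xs = truth["x_center_um"].to_numpy()
    ts = truth["t_center_ms"].to_numpy()
    cx_px = np.round(xs / pixel_size_um).astype(int)
    ct_px = np.round(ts / line_interval_ms).astype(int)

    candidates: list[tuple[int, float, int, int]] = []  # (inside?0:1, dist, ti, rid)
    for region in regions:
        px, pt = region.peak_px
        dx = np.abs(px * pixel_size_um - xs)
        dt = np.abs(pt * line_interval_ms - ts)
        dist = np.hypot(dx / max_dx_um, dt / max_dt_ms)
        near = np.nonzero((dx <= max_dx_um) & (dt <= max_dt_ms))[0]
        for ti in near:
            candidates.append((1, float(dist[ti]), int(ti), region.id))
        # centre-inside test, restricted to truths whose centre pixel is in
        # the region bounding box
        x0, x1, t0, t1 = region.bbox
        maybe = np.nonzero((cx_px >= x0) & (cx_px < x1) & (ct_px >= t0) & (ct_px < t1))[0]
        for ti in maybe:
            if region.contains(cx_px[ti], ct_px[ti]):
                candidates.append((0, float(dist[ti]), int(ti), region.id))

    candidates.sort()
    used_truth: set[int] = set()
    used_region: set[int] = set()
    pairs: dict[int, int] = {}
    for _, _, ti, rid in candidates:
        if ti in used_truth or rid in used_region:
            continue
        pairs[ti] = rid
        used_truth.add(ti)
        used_region.add(rid)
    false_negatives = [i for i in range(n_truth) if i not in used_truth]
    false_positives = [r.id for r in regions if r.id not in used_region]
    return MatchResult(pairs, false_negatives, false_positives)


def sensitivity_by_amplitude(
    batches: list[tuple[pd.DataFrame, MatchResult]],
) -> pd.DataFrame:
    """Fraction of ground-truth sparks detected, per true amplitude.

    ``batches`` pairs each experiment's truth table with its match result;
    results are pooled over experiments.
    """
    rows: list[tuple[float, bool]] = []
    for truth, match in batches:
        amplitudes = truth["amplitude"].to_numpy()
        for i, R in enumerate(amplitudes):
            rows.append((float(R), i in match.pairs))
    df = pd.DataFrame(rows, columns=["amplitude", "detected"])
    out = (
        df.groupby("amplitude")["detected"]
        .agg(sensitivity="mean", n_sparks="size")
        .reset_index()
    )
    return out


def fp_frequency(
    fp_amplitudes: np.ndarray,
    cutoffs: np.ndarray,
    scan_length_um: float,
    scan_duration_s: float,
    n_experiments: int = 1,
) -> pd.DataFrame:
    """Cumulative false-positive frequency above each cutoff amplitude.

    ``freq(c) = #{FP with estimated amplitude >= c} / (duration * length/100)``
    in sparks/(s*100 um), averaged over ``n_experiments`` if the FP list is
    pooled.
    """
    if scan_length_um <= 0 or scan_duration_s <= 0:
        raise ValueError("scan extent must be positive")
    fp = np.asarray(fp_amplitudes, dtype=np.float64)
    norm = scan_duration_s * (scan_length_um / 100.0) * n_experiments
    freqs = [(fp >= c).sum() / norm for c in np.atleast_1d(cutoffs)]
    return pd.DataFrame({"cutoff": np.atleast_1d(cutoffs), "fp_frequency": freqs})


def ppv_by_estimated_amplitude(
    tp_amplitudes: np.ndarray,
    fp_amplitudes: np.ndarray,
    bin_width: float = 0.05,
    min_events: int = 20,
) -> pd.DataFrame:
    """Positive predictive value per estimated-amplitude bin.

    Amplitudes are binned with the given width; only bins with more than
    ``min_events`` events (true or false positives) are reported.  PPV is
    in percent.
    """
    tp = np.asarray(tp_amplitudes, dtype=np.float64)
    fp = np.asarray(fp_amplitudes, dtype=np.float64)
    all_amp = np.concatenate([tp, fp])
    if all_amp.size == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "n_events", "ppv_percent"])
    idx_all = np.floor(all_amp / bin_width).astype(int)
    idx_tp = np.floor(tp / bin_width).astype(int)
    rows = []
    for b in np.unique(idx_all):
        n_events = int((idx_all == b).sum())
        if n_events <= min_events:
            continue
        n_tp = int((idx_tp == b).sum())
        rows.append((b * bin_width, (b + 1) * bin_width, n_events, 100.0 * n_tp / n_events))
    return pd.DataFrame(rows, columns=["bin_left", "bin_right", "n_events", "ppv_percent"])


def morphology_recovery(
    records: pd.DataFrame,
    min_sparks: int = 25,
) -> pd.DataFrame:
    """Mean estimated morphology per (noise level, true amplitude) condition.

    ``records`` needs one row per matched spark with columns ``snr``,
    ``true_amplitude``, ``amplitude``, ``fdhm_ms``, ``fwhm_um``.  Conditions
    with fewer than ``min_sparks`` detected sparks are suppressed.  Means
    are reported with their standard errors; width means ignore sparks
    whose half-max fit failed (NaN widths).
    """
    def sem(x: pd.Series) -> float:
        x = x.dropna()
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")

    grouped = records.groupby(["snr", "true_amplitude"])
    out = grouped.agg(
        n_sparks=("amplitude", "size"),
        mean_amplitude=("amplitude", "mean"),
        sem_amplitude=("amplitude", sem),
        mean_fdhm_ms=("fdhm_ms", "mean"),
        sem_fdhm_ms=("fdhm_ms", sem),
        mean_fwhm_um=("fwhm_um", "mean"),
        sem_fwhm_um=("fwhm_um", sem),
    ).reset_index()
    return out[out["n_sparks"] >= min_sparks].reset_index(drop=True)
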