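"""Baseline fluorescence estimation and variance-stabilizing correction.

The baseline F0 is the slowly varying background fluorescence at each
spatial position.  It is estimated by fitting, independently for every
spatial row, a cubic least-squares spline in time with knots a few seconds
apart, while excluding pixels that belong to detected sparks.  Because the
sparks are not known before the baseline is, the estimate is iterative:
fit F0, stabilize the variance, detect candidate sparks, exclude them,
refit — until the exclusion mask stops changing.

For photon-counting (Poisson) data the correction

    corrected = (image - F0) / sqrt(F0)

gives noise of approximately unit variance everywhere, so a single
SD-multiple threshold is meaningful across the whole image even when the
baseline brightness varies several-fold along the cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LSQUnivariateSpline

from .core import DetectionParams, ExperimentStage, LinescanImage

__all__ = [
    "BackgroundModel",
    "fit_background_once",
    "correct_image",
    "estimate_background",
]

log = logging.getLogger(__name__)

#: F0 values are clipped to this floor (counts) before division.
F0_FLOOR = 0.1


@dataclass
class BackgroundModel:
    """Estimated baseline and the spark exclusion mask used to fit it.

    Attributes
    ----------
    F0
        Baseline fluorescence, same shape as the analyzed stage, on the
        dark-subtracted count scale; positive everywhere.
    spark_mask
        Boolean mask of pixels excluded from the final fit (detected
        spark regions).
    n_iterations_run, converged
        Bookkeeping of the iterative fit.
    """

    F0: np.ndarray
    spark_mask: np.ndarray
    n_iterations_run: int
    converged: bool


def _interior_knots(t: np.ndarray, knot_spacing_s: float) -> np.ndarray:
    # First/last knots inset half a spacing from the stage edges.
    lo = t[0] + 0.5 * knot_spacing_s
    hi = t[-1] - 0.5 * knot_spacing_s
    if hi < lo:
        return np.empty(0)
    n = int(np.floor((hi - lo) / knot_spacing_s)) + 1
    return lo + knot_spacing_s * np.arange(n)


def _fit_row(t: np.ndarray, y: np.ndarray, knots: np.ndarray, t_all: np.ndarray) -> np.ndarray:
    """Cubic LSQ spline of one spatial row, with graceful degradation.

    If the surviving pixels cannot support the requested knot vector
    (Schoenberg-Whitney violation), knots are thinned; the ultimate
    fallback is the row mean.
    """
    while True:
        if t.size > knots.size + 4 and knots.size > 0:
            try:
                spline = LSQUnivariateSpline(t, y, knots, k=3)
                return spline(t_all)
            except ValueError:
                pass
        if knots.size == 0:
            if t.size >= 4:
                coeff = np.polynomial.polynomial.polyfit(t, y, 3)
                return np.polynomial.polynomial.polyval(t_all, coeff)
            log.warning("row has too few unmasked pixels for a spline; using mean")
            return np.full(t_all.shape, y.mean() if y.size else 0.0)
        knots = knots[::2]


def fit_background_once(
    image_sub: np.ndarray,
    exclude_mask: np.ndarray | None,
    knot_spacing_s: float,
    line_interval_ms: float,
) -> np.ndarray:
    """One pass of the baseline fit on a dark-subtracted image.

    For each spatial row, a cubic least-squares spline in time with
    uniformly spaced interior knots (``knot_spacing_s`` apart) is fitted to
    the non-excluded pixels of that row and evaluated at every time point.
    The knot spacing should be considerably larger than the expected spark
    duration, otherwise the baseline absorbs the sparks.

    Returns the fitted baseline, same shape as ``image_sub``, as float64.
    """
    image_sub = np.asarray(image_sub)
    n_x, n_t = image_sub.shape
    t_all = np.arange(n_t) * (line_interval_ms / 1000.0)
    knots = _interior_knots(t_all, knot_spacing_s)
    F0 = np.empty((n_x, n_t))
    if exclude_mask is None:
        keep_all = None
    else:
        keep_all = ~np.asarray(exclude_mask, dtype=bool)
    for i in range(n_x):
        if keep_all is None:
            t, y = t_all, image_sub[i].astype(np.float64)
        else:
            keep = keep_all[i]
            t, y = t_all[keep], image_sub[i][keep].astype(np.float64)
        F0[i] = _fit_row(t, y, knots, t_all)
    return F0


def correct_image(image_sub: np.ndarray, F0: np.ndarray) -> np.ndarray:
    """Variance-stabilizing correction ``(image - F0) / sqrt(F0)``.

    Non-positive baseline values are clipped to a small positive floor
    before the division.
    """
    F0 = np.asarray(F0, dtype=np.float64)
    if np.any(F0 < F0_FLOOR):
        log.warning("baseline contains values below %.2g counts; clipping", F0_FLOOR)
        F0 = np.maximum(F0, F0_FLOOR)
    return (np.asarray(image_sub, dtype=np.float64) - F0) / np.sqrt(F0)


def estimate_background(
    image: LinescanImage,
    stage: ExperimentStage,
    params: DetectionParams | None = None,
) -> BackgroundModel:
    """Iteratively estimate the baseline with detected sparks excluded.

    Each iteration fits F0 to the non-masked pixels, stabilizes the
    variance, smooths, detects candidate spark regions and replaces the
    mask with their union.  Iteration stops when the mask is unchanged,
    when the maximal relative change of F0 drops below
    ``params.convergence_tol``, or after ``params.max_iterations``.
    The returned F0 is always fitted with the final mask excluded.
    """
    # imported here to avoid a circular import: detection uses correct_image
    from .detection import SD_EPS, find_spark_regions, regions_to_mask, smooth_image, threshold_masks

    if params is None:
        params = DetectionParams()
    stage.validate_for(image)
    sub = image.dark_subtracted()[:, stage.start_line : stage.end_line]

    mask = np.zeros(sub.shape, dtype=bool)
    F0_prev: np.ndarray | None = None
    converged = False
    fit_is_final = False
    n_iter = 0
    for n_iter in range(1, params.max_iterations + 1):
        F0 = fit_background_once(
            sub, mask if mask.any() else None, params.knot_spacing_s, image.line_interval_ms
        )
        F0 = np.maximum(F0, F0_FLOOR)
        corrected = correct_image(sub, F0)
        smoothed = smooth_image(corrected, params.median_size_px, params.boxcar_size_px)
        sd = float(smoothed.std())
        if sd <= SD_EPS:
            log.warning("corrected image has zero variance; no sparks to exclude")
            return BackgroundModel(F0, np.zeros(sub.shape, bool), n_iter, True)
        region_mask, peak_mask = threshold_masks(smoothed, sd, params)
        regions = find_spark_regions(
            region_mask, peak_mask, smoothed, params.min_region_px, params.connectivity
        )
        new_mask = regions_to_mask(regions, sub.shape)
        if np.array_equal(new_mask, mask):
            # fixed point: the fit already excluded exactly this mask
            converged = True
            fit_is_final = True
            break
        if F0_prev is not None:
            rel_change = float(np.max(np.abs(F0 - F0_prev) / np.maximum(F0_prev, F0_FLOOR)))
            if rel_change < params.convergence_tol:
                converged = True
                mask = new_mask
                break
        F0_prev = F0
        mask = new_mask
    else:
        log.info("background estimation stopped at max_iterations=%d", params.max_iterations)

    if not fit_is_final:
        # Contract: returned F0 is fitted with the final mask excluded.
        F0 = fit_background_once(
            sub, mask if mask.any() else None, params.knot_spacing_s, image.line_interval_ms
        )
        F0 = np.maximum(F0, F0_FLOOR)
    return BackgroundModel(F0, mask, n_iter, converged)
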