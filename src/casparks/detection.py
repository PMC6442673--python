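"""Threshold-based spark detection on variance-stabilized images.

After baseline subtraction and variance stabilization the noise has
(approximately) unit variance everywhere, so sparks can be segmented with
global thresholds expressed as multiples of the image standard deviation:

* a spark *region* is a connected set of pixels brighter than
  ``spark_intensity`` x SD (2.0 by default),
* a region is accepted only if it is at least ``min_region_px`` pixels
  large (40 by default) and contains at least one pixel brighter than
  ``spark_peak_intensity`` x SD (3.8 by default) that survives a median
  filter of the peak mask — the median filter discards peaks carried by a
  single high-value pixel.

The image is smoothed with a median filter followed by a boxcar (uniform)
filter before thresholding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .background import BackgroundModel, correct_image, estimate_background
from .core import DetectionParams, ExperimentStage, LinescanImage

__all__ = [
    "SparkRegion",
    "DetectionResult",
    "smooth_image",
    "threshold_masks",
    "find_spark_regions",
    "regions_to_mask",
    "detect",
]

log = logging.getLogger(__name__)

_STRUCTURE = {4: ndimage.generate_binary_structure(2, 1), 8: np.ones((3, 3), bool)}

#: SD below this is numerical residue of a constant image, not signal
#: (counts are integers, so any real noise gives SD far above it).
SD_EPS = 1e-8


@dataclass
class SparkRegion:
    """A connected suprathreshold region accepted as a spark candidate.

    Coordinates are pixel/line indices within the analyzed stage.
    ``bbox`` is half-open: ``(x0, x1, t0, t1)``.
    """

    id: int
    xs: np.ndarray
    ts: np.ndarray
    bbox: tuple[int, int, int, int]
    peak_px: tuple[int, int]

    @property
    def n_pixels(self) -> int:
        return int(self.xs.size)

    def contains(self, x: int, t: int) -> bool:
        return bool(np.any((self.xs == x) & (self.ts == t)))


@dataclass
class DetectionResult:
    """Output of one detection run on a stage."""

    regions: list[SparkRegion]
    background: BackgroundModel
    corrected: np.ndarray
    smoothed: np.ndarray
    sd: float
    params: DetectionParams = field(default_factory=DetectionParams)


def smooth_image(
    corrected: np.ndarray, median_size_px: int = 3, boxcar_size_px: int = 3
) -> np.ndarray:
    """Median filter followed by a boxcar (uniform mean) filter.

    Edges are handled by reflection.  Kernel sizes must be odd and no
    larger than the image.
    """
    corrected = np.asarray(corrected, dtype=np.float32)
    for name, size in (("median", median_size_px), ("boxcar", boxcar_size_px)):
        if size % 2 == 0 or size < 1:
            raise ValueError(f"{name} kernel size must be odd >= 1, got {size}")
        if size > min(corrected.shape):
            raise ValueError(f"{name} kernel {size} larger than image {corrected.shape}")
    out = ndimage.median_filter(corrected, size=median_size_px, mode="reflect")
    out = ndimage.uniform_filter(out, size=boxcar_size_px, mode="reflect")
    return out


def _binary_median(mask: np.ndarray, size: int) -> np.ndarray:
    # Median of a binary image == majority vote over the window; integer
    # counting keeps it exact.
    counts = ndimage.uniform_filter(
        mask.astype(np.float32), size=size, mode="reflect"
    ) * (size * size)
    return counts > (size * size) / 2.0 - 0.25


def threshold_masks(
    smoothed: np.ndarray, sd: float, params: DetectionParams
) -> tuple[np.ndarray, np.ndarray]:
    """Dual thresholding of the smoothed corrected image.

    Returns ``(region_mask, peak_mask)``: pixels above
    ``spark_intensity * sd``, and pixels above ``spark_peak_intensity * sd``
    after a median filter that suppresses isolated single-pixel peaks.
    The region mask is deliberately *not* median filtered; small regions
    are handled by the minimal-size rule instead.
    """
    if sd <= SD_EPS:
        log.warning("zero SD: no detectable structure, returning empty masks")
        empty = np.zeros(smoothed.shape, bool)
        return empty, empty.copy()
    region_mask = smoothed > params.spark_intensity * sd
    peak_raw = smoothed > params.spark_peak_intensity * sd
    peak_mask = _binary_median(peak_raw, params.peak_median_size_px)
    return region_mask, peak_mask


def find_spark_regions(
    region_mask: np.ndarray,
    peak_mask: np.ndarray,
    smoothed: np.ndarray,
    min_region_px: int = 40,
    connectivity: int = 8,
) -> list[SparkRegion]:
    """Label connected components and apply the size and peak rules.

    Components with fewer than ``min_region_px`` pixels, or without any
    surviving peak pixel, are discarded.  The region peak is the maximum
    of the smoothed image within the component (ties broken towards the
    earliest time, then the smallest spatial index).  Regions are returned
    ordered by peak time.
    """
    if region_mask.shape != peak_mask.shape:
        raise ValueError("region and peak masks must have the same shape")
    labels, n_labels = ndimage.label(region_mask, structure=_STRUCTURE[connectivity])
    if n_labels == 0:
        return []
    sizes = np.bincount(labels.ravel(), minlength=n_labels + 1)
    has_peak = np.zeros(n_labels + 1, bool)
    peak_labels = labels[peak_mask & region_mask]
    has_peak[np.unique(peak_labels)] = True
    has_peak[0] = False
    keep = np.flatnonzero((sizes >= min_region_px) & has_peak)

    regions: list[SparkRegion] = []
    if keep.size == 0:
        return regions
    slices = ndimage.find_objects(labels)
    # work in (t, x) order so argmax tie-breaking favours earliest time
    smoothed_T = smoothed.T
    labels_T = labels.T
    for lab in keep:
        sl_x, sl_t = slices[lab - 1]
        box = (sl_x.start, sl_x.stop, sl_t.start, sl_t.stop)
        sub_lab = labels_T[sl_t, sl_x]
        inside = sub_lab == lab
        vals = np.where(inside, smoothed_T[sl_t, sl_x], -np.inf)
        flat = int(np.argmax(vals))
        dt, dx = np.unravel_index(flat, vals.shape)
        peak = (sl_x.start + int(dx), sl_t.start + int(dt))
        ts_l, xs_l = np.nonzero(inside)
        regions.append(
            SparkRegion(
                id=-1,
                xs=(xs_l + sl_x.start).astype(np.intp),
                ts=(ts_l + sl_t.start).astype(np.intp),
                bbox=box,
                peak_px=peak,
            )
        )
    regions.sort(key=lambda r: (r.peak_px[1], r.peak_px[0]))
    for i, region in enumerate(regions):
        region.id = i
    return regions


def regions_to_mask(regions: list[SparkRegion], shape: tuple[int, int]) -> np.ndarray:
    """Union of region pixel sets as a boolean mask."""
    mask = np.zeros(shape, bool)
    for region in regions:
        mask[region.xs, region.ts] = True
    return mask


def detect(
    image: LinescanImage,
    stage: ExperimentStage | None = None,
    params: DetectionParams | None = None,
) -> DetectionResult:
    """Run the full spark detection pipeline on one stage.

    Estimates the baseline iteratively (excluding candidate sparks), then
    performs a final variance stabilization, smoothing, dual thresholding
    and connected-component extraction.  Deterministic for fixed input.
    """
    if params is None:
        params = DetectionParams()
    if stage is None:
        stage = ExperimentStage.full(image)
    background = estimate_background(image, stage, params)
    sub = image.dark_subtracted()[:, stage.start_line : stage.end_line]
    corrected = correct_image(sub, background.F0)
    smoothed = smooth_image(corrected, params.median_size_px, params.boxcar_size_px)
    sd = float(smoothed.std())
    region_mask, peak_mask = threshold_masks(smoothed, sd, params)
    regions = find_spark_regions(
        region_mask, peak_mask, smoothed, params.min_region_px, params.connectivity
    )
    return DetectionResult(
        regions=regions,
        background=background,
        corrected=corrected,
        smoothed=smoothed,
        sd=sd,
        params=params,
    )
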