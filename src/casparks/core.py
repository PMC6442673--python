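"""Core domain types for line-scan calcium spark analysis.

A line-scan (xt) recording is a 2-D image in which one spatial line is
acquired repeatedly over time.  Throughout the package the canonical array
layout is ``data[x, t]``: axis 0 is space, axis 1 is time.  Physical
calibration (pixel size in micrometres, line interval in milliseconds) and
the detector dark count travel with the pixel data in
:class:`LinescanImage`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import tifffile

__all__ = [
    "LinescanImage",
    "ExperimentStage",
    "DetectionParams",
    "StageStatistics",
    "read_linescan",
    "write_linescan",
    "stage_statistics",
]


@dataclass(frozen=True)
class LinescanImage:
    """A single-channel line-scan recording with physical calibration.

    Parameters
    ----------
    data
        2-D array of non-negative integer photon counts indexed ``[x, t]``.
    pixel_size_um
        Size of one spatial pixel in micrometres.
    line_interval_ms
        Time between successive lines in milliseconds.
    dark_count
        Detector offset in counts, measured in the absence of illumination.
        It is subtracted from the raw counts before any analysis.
    """

    data: np.ndarray
    pixel_size_um: float
    line_interval_ms: float
    dark_count: float = 0.0

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 2:
            raise ValueError(f"line-scan data must be 2-D, got shape {data.shape}")
        if not np.issubdtype(data.dtype, np.integer):
            raise ValueError(f"line-scan counts must be integer, got dtype {data.dtype}")
        if data.size and data.min() < 0:
            raise ValueError("line-scan counts must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.line_interval_ms <= 0:
            raise ValueError("line_interval_ms must be positive")
        if self.dark_count < 0:
            raise ValueError("dark_count must be non-negative")
        object.__setattr__(self, "data", data)

    @property
    def n_x(self) -> int:
        return self.data.shape[0]

    @property
    def n_t(self) -> int:
        return self.data.shape[1]

    @property
    def length_um(self) -> float:
        """Spatial extent of the scanned line in micrometres."""
        return self.n_x * self.pixel_size_um

    @property
    def duration_s(self) -> float:
        """Duration of the recording in seconds."""
        return self.n_t * self.line_interval_ms / 1000.0

    def dark_subtracted(self) -> np.ndarray:
        """Counts with the detector dark count removed, as float32."""
        return self.data.astype(np.float32) - np.float32(self.dark_count)


@dataclass(frozen=True)
class ExperimentStage:
    """A time interval of the experiment, spanning the full spatial extent.

    The interval is half-open in line indices: ``[start_line, end_line)``.
    """

    start_line: int
    end_line: int
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start_line < self.end_line:
            raise ValueError(
                f"invalid stage interval [{self.start_line}, {self.end_line})"
            )

    @property
    def n_lines(self) -> int:
        return self.end_line - self.start_line

    def validate_for(self, image: LinescanImage) -> None:
        if self.end_line > image.n_t:
            raise ValueError(
                f"stage end {self.end_line} exceeds image length {image.n_t}"
            )

    @classmethod
    def full(cls, image: LinescanImage, label: str = "") -> "ExperimentStage":
        """Stage covering the entire recording."""
        return cls(0, image.n_t, label)


def _check_odd(name: str, value: int) -> None:
    if value < 1 or value % 2 == 0:
        raise ValueError(f"{name} must be an odd integer >= 1, got {value}")


@dataclass
class DetectionParams:
    """Every tunable setting of the spark detection algorithm.

    Thresholds are multiples of the standard deviation (SD) of the smoothed,
    variance-stabilized image: a spark is a connected region brighter than
    ``spark_intensity`` x SD containing at least one pixel brighter than
    ``spark_peak_intensity`` x SD that survives a median filter of the peak
    mask.
    """

    spark_intensity: float = 2.0
    spark_peak_intensity: float = 3.8
    min_region_px: int = 40
    knot_spacing_s: float = 5.0
    median_size_px: int = 5
    boxcar_size_px: int = 5
    peak_median_size_px: int = 5
    max_iterations: int = 5
    convergence_tol: float = 1e-3
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not self.spark_intensity > 0:
            raise ValueError("spark_intensity must be positive")
        if not self.spark_peak_intensity > self.spark_intensity:
            raise ValueError("spark_peak_intensity must exceed spark_intensity")
        if self.min_region_px < 1:
            raise ValueError("min_region_px must be >= 1")
        if self.knot_spacing_s <= 0:
            raise ValueError("knot_spacing_s must be positive")
        _check_odd("median_size_px", self.median_size_px)
        _check_odd("boxcar_size_px", self.boxcar_size_px)
        _check_odd("peak_median_size_px", self.peak_median_size_px)
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DetectionParams":
        return cls(**d)


@dataclass(frozen=True)
class StageStatistics:
    """Summary of the raw counts in one stage.

    ``p001`` and ``p999`` are the 0.1% and 99.9% percentiles; they bracket
    the signal range without being sensitive to single spurious pixels the
    way the minimum and maximum are.
    """

    mean: float
    minimum: float
    maximum: float
    p001: float
    p999: float


def stage_statistics(image: LinescanImage, stage: ExperimentStage) -> StageStatistics:
    """Compute summary statistics of raw counts over one experiment stage.

    Statistics are taken over all pixels of the stage on the raw counts (no
    dark subtraction).  Percentiles use linear interpolation between order
    statistics.
    """
    stage.validate_for(image)
    block = image.data[:, stage.start_line : stage.end_line]
    if block.size == 0:
        raise ValueError("stage contains no pixels")
    p001, p999 = np.percentile(block, [0.1, 99.9])
    return StageStatistics(
        mean=float(block.mean()),
        minimum=float(block.min()),
        maximum=float(block.max()),
        p001=float(p001),
        p999=float(p999),
    )


def read_linescan(
    path,
    pixel_size_um: float,
    line_interval_ms: float,
    dark_count: float = 0.0,
    time_major: bool = False,
) -> LinescanImage:
    """Read a single-plane grayscale TIFF as a line-scan image.

    Parameters
    ----------
    time_major
        If True the file stores lines as rows (``[t, x]``) and is transposed
        into the canonical ``[x, t]`` layout.
    """
    data = tifffile.imread(str(path))
    if data.ndim != 2:
        raise ValueError(
            f"unsupported TIFF: expected a single grayscale plane, "
            f"got shape {data.shape}"
        )
    if time_major:
        data = data.T
    return LinescanImage(
        data=np.ascontiguousarray(data),
        pixel_size_um=pixel_size_um,
        line_interval_ms=line_interval_ms,
        dark_count=dark_count,
    )


def write_linescan(path, image: LinescanImage, time_major: bool = False) -> None:
    """Write a line-scan image as a single-plane grayscale TIFF."""
    data = image.data.T if time_major else image.data
    tifffile.imwrite(str(path), np.ascontiguousarray(data))
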