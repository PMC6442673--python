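"""Convenience wrappers chaining detection, morphology and tabulation."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import DetectionParams, ExperimentStage, LinescanImage
from .detection import DetectionResult, detect
from .morphology import SparkProperties, make_roi, normalized_fluorescence, spark_properties

__all__ = ["analyze", "sparks_to_frame"]


def analyze(
    image: LinescanImage,
    stage: ExperimentStage | None = None,
    params: DetectionParams | None = None,
    pad_factor: float = 0.5,
) -> tuple[DetectionResult, list[SparkProperties]]:
    """Detect sparks in one stage and fit the morphology of each."""
    if stage is None:
        stage = ExperimentStage.full(image)
    result = detect(image, stage, params)
    shape = result.smoothed.shape
    sub = image.dark_subtracted()[:, stage.start_line : stage.end_line]
    dFF0 = normalized_fluorescence(sub, result.background.F0)
    props = []
    for region in result.regions:
        roi = make_roi(region, shape, pad_factor)
        props.append(
            spark_properties(
                image, result.background, roi, region.peak_px, stage, dFF0=dFF0
            )
        )
    return result, props


def sparks_to_frame(
    result: DetectionResult,
    props: list[SparkProperties],
    image: LinescanImage,
) -> pd.DataFrame:
    """One row per detected spark: region geometry plus fitted morphology."""
    rows = []
    for region, p in zip(result.regions, props):
        x0, x1, t0, t1 = region.bbox
        rows.append(
            {
                "region_id": region.id,
                "n_pixels": region.n_pixels,
                "x0": x0,
                "x1": x1,
                "t0": t0,
                "t1": t1,
                "peak_x_px": region.peak_px[0],
                "peak_t_px": region.peak_px[1],
                "peak_x_um": p.peak_x_um,
                "peak_t_ms": p.peak_t_ms,
                "amplitude": p.amplitude,
                "fwhm_um": p.fwhm_um,
                "fdhm_ms": p.fdhm_ms,
                "fit_ok_temporal": p.fit_ok_temporal,
                "fit_ok_spatial": p.fit_ok_spatial,
                "accepted": p.accepted,
            }
        )
    columns = [
        "region_id", "n_pixels", "x0", "x1", "t0", "t1",
        "peak_x_px", "peak_t_px", "peak_x_um", "peak_t_ms",
        "amplitude", "fwhm_um", "fdhm_ms",
        "fit_ok_temporal", "fit_ok_spatial", "accepted",
    ]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows, columns=columns)
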