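"""Experiment-level spark statistics for pharmacological comparisons.

These are the summaries used to compare conditions (e.g. control vs a
beta-adrenergic agonist): cumulative spark frequency above a cutoff
amplitude, the same restricted to long sparks, the frequency of multi-spark
groups (repeated release from one site), and morphology distributions
within a fixed amplitude window.  All frequencies are expressed in
sparks/(s*100 um) so recordings of different extent are comparable.

Amplitude cutoffs use >= semantics throughout.  Statistical testing of the
exported tables is left to external tools.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CUTOFFS",
    "cumulative_frequency",
    "long_spark_frequency",
    "spark_groups",
    "amplitude_window_summary",
]

#: Default cutoff grid of F0-normalized amplitudes.
DEFAULT_CUTOFFS: tuple[float, ...] = (0.5, 0.75, 1.0, 1.25, 1.5)


def _norm(scan_length_um: float, duration_s: float) -> float:
    if scan_length_um <= 0 or duration_s <= 0:
        raise ValueError("scan length and duration must be positive")
    return duration_s * (scan_length_um / 100.0)


def cumulative_frequency(
    sparks: pd.DataFrame,
    cutoffs=DEFAULT_CUTOFFS,
    scan_length_um: float = 0.0,
    duration_s: float = 0.0,
) -> pd.DataFrame:
    """Frequency of sparks with amplitude >= cutoff, per cutoff.

    ``sparks`` needs an ``amplitude`` column (units of F0).  Frequencies
    are in sparks/(s*100 um).
    """
    norm = _norm(scan_length_um, duration_s)
    amp = sparks["amplitude"].to_numpy(dtype=np.float64)
    cutoffs = np.atleast_1d(np.asarray(cutoffs, dtype=np.float64))
    freq = [(amp >= c).sum() / norm for c in cutoffs]
    return pd.DataFrame({"cutoff": cutoffs, "frequency": freq})


def long_spark_frequency(
    sparks: pd.DataFrame,
    cutoffs=DEFAULT_CUTOFFS,
    fdhm_min_ms: float = 25.0,
    scan_length_um: float = 0.0,
    duration_s: float = 0.0,
) -> pd.DataFrame:
    """Cumulative frequency restricted to sparks with FDHM >= ``fdhm_min_ms``."""
    long = sparks[sparks["fdhm_ms"] >= fdhm_min_ms]
    return cumulative_frequency(long, cutoffs, scan_length_um, duration_s)


def spark_groups(
    sparks: pd.DataFrame,
    max_dt_s: float = 2.0,
    max_dx_um: float = 1.0,
    min_size: int = 2,
    cutoff: float = 0.0,
    scan_length_um: float = 0.0,
    duration_s: float = 0.0,
) -> pd.DataFrame:
    """Count chains of sparks recurring at (nearly) one location.

    Sparks with amplitude >= ``cutoff`` are scanned in time order.  A group
    is a maximal chain in which each successive member occurs less than
    ``max_dt_s`` after the previous member and within ``max_dx_um`` of the
    *first* member's location.  Each spark belongs to at most one group
    (earliest-start wins).  Groups with at least ``min_size`` members are
    counted; the frequency is normalized like :func:`cumulative_frequency`.

    ``sparks`` needs columns ``amplitude``, ``peak_x_um`` and ``peak_t_ms``.
    """
    norm = _norm(scan_length_um, duration_s)
    sel = sparks[sparks["amplitude"] >= cutoff].sort_values("peak_t_ms")
    x = sel["peak_x_um"].to_numpy(dtype=np.float64)
    t = sel["peak_t_ms"].to_numpy(dtype=np.float64) / 1000.0
    n = len(sel)
    assigned = np.zeros(n, dtype=bool)
    n_groups = 0
    group_sizes: list[int] = []
    for i in range(n):
        if assigned[i]:
            continue
        assigned[i] = True
        anchor_x = x[i]
        last_t = t[i]
        size = 1
        for j in range(i + 1, n):
            if assigned[j]:
                continue
            if t[j] - last_t >= max_dt_s:
                break
            if abs(x[j] - anchor_x) <= max_dx_um:
                assigned[j] = True
                last_t = t[j]
                size += 1
        if size >= min_size:
            n_groups += 1
            group_sizes.append(size)
    return pd.DataFrame(
        {
            "cutoff": [cutoff],
            "min_size": [min_size],
            "n_groups": [n_groups],
            "frequency": [n_groups / norm],
        }
    )


def amplitude_window_summary(
    sparks: pd.DataFrame,
    window: tuple[float, float] = (0.8, 1.2),
    bins: tuple[tuple[float, float], ...] = ((0.8, 1.0), (1.0, 1.2)),
) -> pd.DataFrame:
    """FDHM/FWHM summaries for sparks inside a fixed amplitude window.

    Sparks with amplitude in ``[window[0], window[1]]`` are split into the
    given amplitude bins (lower edge inclusive; the last bin also includes
    its upper edge).  Returns per-bin counts and means, one row per bin;
    the per-spark values stay available by filtering the input frame.
    """
    lo, hi = window
    inside = sparks[(sparks["amplitude"] >= lo) & (sparks["amplitude"] <= hi)]
    rows = []
    for k, (b_lo, b_hi) in enumerate(bins):
        last = k == len(bins) - 1
        if last:
            sel = inside[(inside["amplitude"] >= b_lo) & (inside["amplitude"] <= b_hi)]
        else:
            sel = inside[(inside["amplitude"] >= b_lo) & (inside["amplitude"] < b_hi)]
        rows.append(
            (
                b_lo,
                b_hi,
                len(sel),
                float(sel["fdhm_ms"].mean()) if len(sel) else float("nan"),
                float(sel["fwhm_um"].mean()) if len(sel) else float("nan"),
            )
        )
    return pd.DataFrame(
        rows, columns=["bin_left", "bin_right", "n_sparks", "mean_fdhm_ms", "mean_fwhm_um"]
    )
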