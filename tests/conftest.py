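import numpy as np
import pytest

from casparks import LinescanImage, SyntheticConfig
from casparks.synthetic import spark_profile


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def flat_poisson_image(rng):
    """Spark-free Poisson image, F0 level 20, modest size."""
    data = rng.poisson(20.0, size=(64, 3000)).astype(np.uint16)
    return LinescanImage(data, pixel_size_um=0.14, line_interval_ms=1.53)


def make_noiseless_spark_image(
    R=1.0,
    f0=100.0,
    n_x=160,
    n_t=2500,
    pixel_size_um=0.14,
    line_interval_ms=1.53,
    xi_um=1.5,
    tau_r_ms=7.0,
    tau_d_ms=18.0,
    x_center_px=None,
    t_center_px=None,
):
    """Quantized noiseless image with one embedded spark (uint16 counts).

    A high baseline keeps the quantization error negligible relative to
    the spark, so profile-fit accuracy can be judged in isolation.
    """
    if x_center_px is None:
        x_center_px = n_x // 2
    if t_center_px is None:
        t_center_px = n_t // 2
    x = (np.arange(n_x) - x_center_px) * pixel_size_um
    t = (np.arange(n_t) - t_center_px) * line_interval_ms
    field = f0 + spark_profile(
        x[:, None], t[None, :], R, f0, xi_um, tau_r_ms, tau_d_ms
    )
    data = np.floor(field + 0.5).astype(np.uint16)
    image = LinescanImage(data, pixel_size_um, line_interval_ms)
    return image, (x_center_px, t_center_px)


@pytest.fixture
def small_synthetic_config():
    """Scaled-down synthetic experiment (fast to analyze)."""
    return SyntheticConfig(n_x=128, n_t=8000, seed=5)
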