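import numpy as np
import pytest

import telefall as tf


@pytest.fixture(scope="session")
def default_layout():
    """Reconstructed reference deployment: 11 x 5.75 m, 18 nodes, 5 generators."""
    return tf.grid_layout()


@pytest.fixture(scope="session")
def class_table():
    return tf.default_class_table()


@pytest.fixture
def flat_trace():
    """Quiet standing: pure 1 G on the vertical axis."""
    n = 1000
    return tf.AccelTrace(ax=np.zeros(n), ay=np.ones(n), az=np.zeros(n))


def make_bump_trace(peak_g: float, n: int = 2000, bump_axis: str = "ay",
                    width: int = 40, center: int = 1000,
                    sample_rate_hz: float = 200.0) -> tf.AccelTrace:
    """Baseline 1 G vertical plus a half-sine bump to ``peak_g`` on one axis."""
    axes = {"ax": np.zeros(n), "ay": np.ones(n), "az": np.zeros(n)}
    i = np.arange(width)
    bump = np.sin(np.pi * i / (width - 1))
    if bump_axis == "ay":
        axes["ay"][center : center + width] += (peak_g - 1.0) * bump
    else:
        axes[bump_axis][center : center + width] += peak_g * bump
    return tf.AccelTrace(sample_rate_hz=sample_rate_hz, **axes)
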