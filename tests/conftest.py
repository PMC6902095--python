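import numpy as np
import pytest

from satblot.densitometry import SpotLayout
from satblot.synthetic_data import NoiseModel, SignalModel, make_layout, make_membrane


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_signal():
    """Small, easily hand-checked signal law: I = 100 + 20 ln(q) + 10."""
    return SignalModel(
        intercept_a=100.0, slope_b=20.0, q_ref=1.0, saturation_level=1e4, background_level=10.0
    )


@pytest.fixture
def no_noise():
    return NoiseModel(assay_cv=0.0, extraction_cv=0.0, pixel_sd=0.0, gradient_amplitude=0.0, seed=0)


@pytest.fixture
def small_layout():
    """3 standards at {1, e, e^2} pg/ng, 1 background, 2 triplicate samples."""
    return make_layout(
        ["s1", "s2"], standard_contents=[1.0, np.e, np.e**2], radius=6.0, pitch=30.0, grid_rows=5
    )


@pytest.fixture
def noiseless_membrane(small_layout, toy_signal, no_noise):
    contents = {"s1": 1.0, "s2": float(np.e)}
    image, truth = make_membrane(small_layout, contents, toy_signal, no_noise)
    return image, truth, small_layout, contents
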