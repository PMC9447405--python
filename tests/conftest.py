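import numpy as np
import pytest

from spotquant import GridSpec, RasterImage, quantify_array, render_gradient_demo


@pytest.fixture(scope="session")
def gradient_demo():
    """The seeded 7x10 gradient-background demonstration array."""
    img, truth = render_gradient_demo(seed=42)
    return img, truth


@pytest.fixture(scope="session")
def gradient_demo_measurements(gradient_demo):
    img, truth = gradient_demo
    return quantify_array(img, GridSpec(n_rows=7, n_cols=10)), truth


def make_grey(pixels, bit_depth=8):
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    return RasterImage(pixels=np.asarray(pixels, dtype=dtype), bit_depth=bit_depth)
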