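import numpy as np
import pytest

from sludgecolor import (
    CalibrationSample,
    RGBMean,
    build_model,
    reference_calibration_subset,
    reference_dataset,
)


def make_samples(mlss, r=None, g=None, b=None):
    """Build calibration samples from parallel value lists.

    Channels left as None default to the values of the first given channel,
    so single-channel toys stay terse.
    """
    mlss = list(mlss)
    first = next(v for v in (r, g, b) if v is not None)
    r = list(r) if r is not None else list(first)
    g = list(g) if g is not None else list(first)
    b = list(b) if b is not None else list(first)
    return [
        CalibrationSample(f"s{i}", m, RGBMean(rv, gv, bv))
        for i, (m, rv, gv, bv) in enumerate(zip(mlss, r, g, b))
    ]


@pytest.fixture(scope="session")
def ref_full():
    return reference_dataset()


@pytest.fixture(scope="session")
def ref_subset():
    return reference_calibration_subset()


@pytest.fixture(scope="session")
def ref_model(ref_subset):
    return build_model(ref_subset)


@pytest.fixture
def uniform_image():
    def _make(shape=(20, 20), color=(10, 20, 30)):
        img = np.empty((*shape, 3), dtype=np.uint8)
        img[:] = color
        return img

    return _make
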