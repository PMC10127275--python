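import numpy as np
import pytest

import guvquant as gq
from guvquant.regions import SpotRegion


@pytest.fixture(scope="session")
def tirf_model():
    return gq.guvforge.ImagingModel()


@pytest.fixture(scope="session")
def wf_model():
    return gq.pipeline.RunConfig(rng_seed=0).wf_model()


@pytest.fixture(scope="session")
def spot():
    return SpotRegion(cx=255.5, cy=255.5, radius_px=180.0)


@pytest.fixture(scope="session")
def detect_params():
    return gq.pipeline.RunConfig(rng_seed=0).detect_params()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def subtract_offset(frame):
    """Flat camera-offset removal used throughout the image tests."""
    img = np.asarray(frame, dtype=float)
    return img - float(np.median(img))
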