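import numpy as np
import pytest

from cypritrack.config import RunConfig
from cypritrack.imaging import BackgroundModel


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def flat_bg():
    """Uniform bright background, 120x120."""
    return BackgroundModel(pixels=np.full((120, 120), 200.0),
                           diff_threshold=30.0, converged=True)


def make_frame(shape=(120, 120), bg=200.0):
    return np.full(shape, bg, dtype=np.float64)


def paint_square(frame, x0, y0, side=3, value=50.0):
    frame[y0:y0 + side, x0:x0 + side] = value
    return frame
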