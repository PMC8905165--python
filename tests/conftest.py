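import numpy as np
import pytest

from motortrace import io
from motortrace.models import MicrotubuleField, MTSegment, OpticsModel


@pytest.fixture(scope="session")
def cfg754():
    return io.packaged_config("cenpe754")


@pytest.fixture(scope="session")
def cfgfl():
    return io.packaged_config("cenpefl")


@pytest.fixture(scope="session")
def cfg483():
    return io.packaged_config("cenpe483")


@pytest.fixture(scope="session")
def cfg483lz():
    return io.packaged_config("cenpe483lz")


@pytest.fixture
def small_optics():
    """A small, fast field of view for rendering tests."""
    return OpticsModel(duration=12.0, image_shape=(64, 64))


@pytest.fixture
def horizontal_segment():
    """One horizontal microtubule crossing a 64x64 image, 8 µm long."""
    return MTSegment((32.0, 5.0), (32.0, 55.0), 50 * 160 / 1000.0, 1)


@pytest.fixture
def single_mt_field(horizontal_segment):
    return MicrotubuleField((horizontal_segment,))


def staircase(levels, seg_len, unit=100.0):
    """Noiseless staircase trace: each level held for seg_len frames."""
    return np.concatenate([np.full(seg_len, unit * lv, dtype=float) for lv in levels])
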