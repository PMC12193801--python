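import numpy as np
import pytest

from morphodyn.io_config import Calibration, PipelineConfig


@pytest.fixture
def unit_cal() -> Calibration:
    """1 μm/px, 1 s/frame — physical units equal pixel units."""
    return Calibration(pixel_size_um=1.0, frame_interval_s=1.0)


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


def disk_mask(shape, center, radius_px):
    yy, xx = np.indices(shape)
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius_px**2


def square_mask(shape, top_left, side_px):
    out = np.zeros(shape, dtype=bool)
    r, c = top_left
    out[r : r + side_px, c : c + side_px] = True
    return out


@pytest.fixture
def disk():
    return disk_mask


@pytest.fixture
def square():
    return square_mask
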