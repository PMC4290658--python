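import numpy as np
import pytest

from flymuscle.imaging import AcquisitionMetadata


@pytest.fixture
def meta():
    return AcquisitionMetadata(
        stack_name="teststack",
        stock_id="BL-0001",
        genotype="control",
        acquisition_date="2014-03-01",
        sample_location="dish1-pos2",
        pixel_size_um=1.25,
        frame_interval_min=30.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20140301)


def capsule_mask(shape, p0, p1, width):
    """Reference capsule rasteriser used as ground truth in tests."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0:
        return np.hypot(xx - p0[0], yy - p0[1]) <= width / 2
    t = np.clip(((xx - p0[0]) * d[0] + (yy - p0[1]) * d[1]) / L2, 0, 1)
    return np.hypot(xx - (p0[0] + t * d[0]), yy - (p0[1] + t * d[1])) <= width / 2
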