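import numpy as np
import pytest

from calconsensus import CalibrationCurve, CalibrationPoint


def make_curve(xy_pairs, curve_id="c", group="g"):
    """Build a curve from (level, response) pairs."""
    points = tuple(
        CalibrationPoint(level=float(x), response=float(y), replicate=1)
        for x, y in xy_pairs
    )
    return CalibrationCurve(curve_id=curve_id, group=group, points=points)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def collinear_curve():
    return make_curve([(1, 2), (2, 4), (3, 6)])
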