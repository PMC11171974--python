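import numpy as np
import pytest
from shapely.geometry import Polygon

from spatqol.weights import AreaGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)


def square(area_id, x0, y0, size=1.0):
    return AreaGeometry(
        area_id,
        Polygon([(x0, y0), (x0 + size, y0), (x0 + size, y0 + size), (x0, y0 + size)]),
        (x0 + size / 2, y0 + size / 2),
    )


@pytest.fixture
def grid_2x2():
    return [square(f"A{i}", i % 2, i // 2) for i in range(4)]


@pytest.fixture
def grid_3x3():
    return [square(f"A{i}", i % 3, i // 3) for i in range(9)]


def point_areas(xys):
    """Areas with given centroids and small dummy polygons (for
    distance-based constructions where only centroids matter)."""
    out = []
    for i, (x, y) in enumerate(xys):
        poly = Polygon([(x, y), (x + 0.01, y), (x + 0.01, y + 0.01), (x, y + 0.01)])
        out.append(AreaGeometry(f"P{i}", poly, (x, y)))
    return out
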