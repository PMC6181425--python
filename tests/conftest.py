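import numpy as np
import pytest

from woundvertex import ModelParams
from woundvertex.woundgen import generate_tissue


@pytest.fixture
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def honeycomb60():
    return generate_tissue(60, rng=1, kind="honeycomb")


@pytest.fixture(scope="session")
def voronoi60():
    return generate_tissue(60, rng=2, kind="voronoi")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_simple_polygon(rng, n=6, r0=5.0):
    """Star-shaped (hence simple) CCW polygon around the origin."""
    from woundvertex.tissue import polygon_area
    ang = np.sort(rng.uniform(0, 2 * np.pi, n))
    rad = r0 * rng.uniform(0.5, 1.5, n)
    pts = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
    return pts if polygon_area(pts) > 0 else pts[::-1].copy()
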