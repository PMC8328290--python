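import numpy as np
import pytest

from ccshape import Contour, SplineShapeSpec, build_matched_pairs, gen_spline_shape


@pytest.fixture(scope="session")
def matched_bins():
    """Similarity-matched pair corpus, built once for the whole session."""
    return build_matched_pairs(4, rng=5, pool_factor=3.0, max_candidates=1500)


@pytest.fixture
def circle_factory():
    """Closed CCW circle of a given radius, densely sampled."""

    def make(radius=100.0, n=720, center=(0.0, 0.0), ccw=True):
        t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        if not ccw:
            t = t[::-1]
        pts = np.column_stack([center[0] + radius * np.cos(t),
                               center[1] + radius * np.sin(t)])
        return Contour(points=pts, closed=True)

    return make


@pytest.fixture
def spline_shape():
    return gen_spline_shape(SplineShapeSpec(seed=42))


@pytest.fixture
def spline_shape_with_controls():
    return gen_spline_shape(SplineShapeSpec(seed=42), return_controls=True)
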