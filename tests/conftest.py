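import numpy as np
import pytest

from sdmtools import ExtentSpec, FixtureSpec, Grid, OccurrenceSet


@pytest.fixture
def unit_grid10():
    """10x10 unit-cell grid over [0,10]^2, all zeros."""
    return Grid(np.zeros((10, 10)), 0.0, 0.0, 1.0)


@pytest.fixture
def small_spec():
    return FixtureSpec(seed=7, extent=ExtentSpec(0, 0, 40, 40))


def make_occ(points, species="sp", labels=None):
    pts = np.asarray(points, dtype=float)
    return OccurrenceSet.from_arrays(
        [species] * len(pts), pts[:, 0], pts[:, 1], labels
    )


@pytest.fixture
def occ_factory():
    return make_occ
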