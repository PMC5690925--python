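import datetime

import numpy as np
import pytest

from cobaltqa import (
    GridSpec,
    ToleranceConfig,
    default_reference_sources,
    generate_plan,
    simulate_delivery,
)

TREATMENT_DATE = datetime.date(2016, 4, 1)


@pytest.fixture(scope="session")
def plan():
    return generate_plan(1)


@pytest.fixture(scope="session")
def sources():
    return default_reference_sources()


@pytest.fixture(scope="session")
def record(plan, sources):
    return simulate_delivery(plan, sources, TREATMENT_DATE)


@pytest.fixture(scope="session")
def tol(sources):
    return ToleranceConfig(reference_sources=sources)


@pytest.fixture(scope="session")
def coarse_grid():
    # 30 x 30 pixels, one pixel per leaf row: fast and exact for map algebra
    return GridSpec(spacing=1.05, x_extent=31.5, y_extent=31.5, leaf_width=1.05)


def supersample_pixel(leaf_pairs, grid, row, col, sub=100):
    """Independent point-sampling oracle for one pixel's aperture coverage.

    Samples the pixel on a sub x sub lattice (sub=100 at 1 mm spacing is a
    0.01 mm sub-pixel) and classifies each point against the leaf geometry
    directly, without any area arithmetic.
    """
    x_edges, y_edges = grid.x_edges(), grid.y_edges()
    xs = x_edges[col] + (np.arange(sub) + 0.5) * grid.spacing / sub
    ys = y_edges[row] + (np.arange(sub) + 0.5) * grid.spacing / sub
    stack_half = len(leaf_pairs) * grid.leaf_width / 2.0
    inside = 0
    for y in ys:
        i = int((y + stack_half) // grid.leaf_width)
        if 0 <= i < len(leaf_pairs):
            p = leaf_pairs[i]
            inside += int(np.count_nonzero((xs > p.left_x) & (xs < p.right_x)))
    return inside / (sub * sub)
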