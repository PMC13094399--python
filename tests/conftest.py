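import numpy as np
import pytest
import shapely

from heatrisk import (
    Affine,
    ClimateGrid,
    WarmingSpec,
    assemble_scenarios,
    make_baseline,
    make_scenarios,
)


@pytest.fixture(scope="session")
def unit_transform():
    """1°-cell north-up transform with upper-left corner at (0, 10)."""
    return Affine.from_origin(0.0, 10.0, 1.0, 1.0)


@pytest.fixture()
def grid_2x2(unit_transform):
    values = np.array([[30.0, 31.0], [32.0, np.nan]])
    return ClimateGrid(values, unit_transform, label="tiny")


@pytest.fixture()
def grid_5x5(unit_transform):
    """Deterministic 5×5 grid: value = 20 + row + 0.1*col, no nodata."""
    rows, cols = np.meshgrid(np.arange(5), np.arange(5), indexing="ij")
    return ClimateGrid(20.0 + rows + 0.1 * cols, unit_transform, label="g5")


@pytest.fixture(scope="session")
def baseline():
    return make_baseline(seed=11)


@pytest.fixture(scope="session")
def scenarios(baseline):
    return make_scenarios(baseline, WarmingSpec(seed=11))


@pytest.fixture(scope="session")
def uniform_scenarios(baseline):
    """Three scenarios with spatially uniform +1/+2/+3 °C warming."""
    return make_scenarios(
        baseline, WarmingSpec(k_scenarios=3, delta_range=(1.0, 3.0),
                              spatial_pattern="uniform", seed=0))


def cells_polygon(transform, cells):
    """Union of cell rectangles — mirrors the generator's construction."""
    boxes = []
    for r, c in cells:
        x0, y0 = transform.xy(r, c, offset="ul")
        x1, y1 = transform.xy(r + 1, c + 1, offset="ul")
        boxes.append(shapely.box(min(x0, x1), min(y0, y1), max(x0, x1), max(y0, y1)))
    return shapely.unary_union(boxes)
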