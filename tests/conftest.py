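import sys
from pathlib import Path

import numpy as np
import pytest
from shapely.geometry import box

sys.path.insert(0, str(Path(__file__).parent))  # raster_oracle helper

from hnvf import (
    LandCoverFeature,
    LandCoverMap,
    LandscapeUnit,
    PipelineOptions,
    default_registry,
    run_pipeline,
)
from hnvf.synthetic_landscape import SyntheticScenario, generate


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture
def unit_1ha():
    """A 100 m x 100 m landscape unit at the origin."""
    return LandscapeUnit.from_boundary("U1", "one-hectare", box(0, 0, 100, 100))


@pytest.fixture(scope="session")
def municipality():
    """Default synthetic municipality, fixed seed."""
    return generate(SyntheticScenario(seed=7))


@pytest.fixture(scope="session")
def pipeline_output(municipality):
    m = municipality
    return run_pipeline(
        m.landcover, m.units, m.agrarian, m.registry,
        constraints=m.constraints, occurrences=m.occurrences,
        options=PipelineOptions(occurrence_grid_m=m.scenario.occurrence_square_m),
    )


def grid_to_map(grid: np.ndarray, cell_m: float, codes: list[str]) -> LandCoverMap:
    """One feature per grid cell (vector twin of a raster mosaic)."""
    feats = []
    rows, cols = grid.shape
    for r in range(rows):
        for c in range(cols):
            geom = box(c * cell_m, (rows - 1 - r) * cell_m,
                       (c + 1) * cell_m, (rows - r) * cell_m)
            feats.append(LandCoverFeature(geom, codes[int(grid[r, c])]))
    return LandCoverMap(feats)


def grid_unit(grid: np.ndarray, cell_m: float) -> LandscapeUnit:
    rows, cols = grid.shape
    return LandscapeUnit.from_boundary(
        "G", "grid", box(0, 0, cols * cell_m, rows * cell_m)
    )
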