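from pathlib import Path

import numpy as np
import pytest

from breastsym import (
    Point,
    ShapeParams,
    default_weights,
    make_symmetric_pair,
)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture(scope="session")
def default_w():
    return default_weights()


@pytest.fixture()
def symmetric_ann():
    """A mirror-symmetric synthetic annotation with a wiggly contour."""
    return make_symmetric_pair(
        ShapeParams(seed=7, contour_wiggle=0.05, nipple_offset=(8.0, 15.0))
    )


@pytest.fixture(scope="session")
def fixture_params():
    """The exact parameters the shipped symmetric_example.json was built from."""
    return ShapeParams(
        semi_axis_horizontal=110.0,
        semi_axis_vertical=95.0,
        droop=0.15,
        nipple_offset=(5.0, 12.0),
        torso_midline_x=400.0,
        jugulum=Point(400.0, 80.0),
        n_vertices=48,
        seed=20,
        contour_wiggle=0.04,
    )


@pytest.fixture(scope="session")
def shrout_fleiss_matrix() -> np.ndarray:
    """The classic 6-subject x 4-rater reliability demonstration matrix."""
    return np.array(
        [[9, 2, 5, 8], [6, 1, 3, 2], [8, 4, 6, 8], [7, 1, 2, 6], [10, 5, 6, 9], [6, 2, 4, 7]],
        dtype=float,
    )
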