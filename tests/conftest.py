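"""Shared fixtures: small canvases, grids and sessions sized for fast tests."""

import numpy as np
import pytest

from figground.geometry import CanvasGeometry
from figground.session import PositionGrid, build_figure_map_session


@pytest.fixture(scope="session")
def canvas():
    """Full-size rendering canvas (80 x 60 degrees at 2 px/deg)."""
    return CanvasGeometry()


@pytest.fixture(scope="session")
def small_canvas():
    """Reduced canvas for tests that only need a small figure."""
    return CanvasGeometry(width_deg=40.0, height_deg=30.0, px_per_deg=2.0)


@pytest.fixture(scope="session")
def grid():
    """Canonical 16 x 8 position grid, 10 repeats."""
    return PositionGrid()


@pytest.fixture(scope="session")
def canonical_session(grid, canvas):
    """Full 7,680-trial session (trial table only; movies render lazily)."""
    return build_figure_map_session(grid, seed=101, canvas=canvas)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
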