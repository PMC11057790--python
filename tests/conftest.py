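import numpy as np
import pytest

from tumorcast import ExperimentDesign, GridSpec


@pytest.fixture(scope="session")
def grid5() -> GridSpec:
    """Coarse 5x5 grid (same 430-um pixels, smaller field of view)."""
    return GridSpec(n_rows=5, n_cols=5, pixel_size_um=430.0, field_of_view_um=2150.0)


@pytest.fixture(scope="session")
def design5(grid5) -> ExperimentDesign:
    """Miniature experiment: 5x5 grid, 400 seeded cells (same density/pixel
    as 2000 cells on the full 15x15 grid)."""
    return ExperimentDesign(grid=grid5, seed_cells=400)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
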