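import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py


@pytest.fixture
def rng():
    return np.random.default_rng(20190306)


@pytest.fixture
def random_grids(rng):
    """100 random intensity grids of sizes up to 16x16."""
    grids = []
    for _ in range(100):
        n_rows = int(rng.integers(2, 17))
        n_cols = int(rng.integers(2, 17))
        grid = rng.random((n_rows, n_cols))
        # sprinkle exact zeros to exercise the 0 ln 0 limit
        grid[rng.random(grid.shape) < 0.1] = 0.0
        if not np.any(grid > 0):
            grid[0, 0] = 0.5
        grids.append(grid)
    return grids
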