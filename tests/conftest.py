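import numpy as np
import pandas as pd
import pytest

from stochmix import Geometry, seed_cells


@pytest.fixture
def small_geometry() -> Geometry:
    return Geometry(200.0, 200.0, "adherent", 2.0)


@pytest.fixture
def suspension_geometry() -> Geometry:
    return Geometry(200.0, 200.0, "suspension", 2.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def toy_cells() -> pd.DataFrame:
    """Six cells with hand-checkable channel values."""
    return pd.DataFrame(
        {
            "cell_id": range(6),
            "x_um": [10.0, 20, 30, 40, 50, 60],
            "y_um": [10.0, 10, 10, 10, 10, 10],
            "tag": [1.0, 2, 3, 4, 5, 6],
        }
    )
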