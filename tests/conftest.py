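import numpy as np
import pytest

import eai_risk as er


@pytest.fixture(scope="session")
def tables():
    return er.default_tables()


@pytest.fixture(scope="session")
def small_scene():
    """An 80x80 synthetic base scene shared across read-only tests."""
    return er.generate_base_scene(er.SceneSpec(shape=(80, 80), seed=11))


@pytest.fixture
def simple_grid():
    vals = np.arange(12, dtype=float).reshape(3, 4)
    mask = np.zeros((3, 4), dtype=bool)
    mask[0, 0] = True
    return er.Grid(vals, mask, cell_size=500.0, origin=(0.0, 0.0),
                   crs_tag="test")
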