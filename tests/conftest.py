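import numpy as np
import pytest

from flusim.grids import CategoricalRaster
from flusim.synthetic import SyntheticConfig, generate_fixture


def make_lu(values, cell_size=100.0, nodata=-9999):
    """Small categorical raster from a nested list."""
    return CategoricalRaster(np.asarray(values, dtype=np.int32), cell_size,
                             nodata_code=nodata)


@pytest.fixture(scope="session")
def fixture100():
    """Shared 100x100 synthetic landscape (two epochs, drivers, roads)."""
    return generate_fixture(SyntheticConfig(shape=(100, 100), seed=7))


@pytest.fixture(scope="session")
def balanced_fixture():
    """Landscape where every class has learnable support."""
    cfg = SyntheticConfig(
        shape=(100, 100), seed=13,
        class_prevalence=np.array([0.3, 0.2, 0.2, 0.1, 0.15, 0.05]),
    )
    return generate_fixture(cfg)
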