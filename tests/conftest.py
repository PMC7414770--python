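import numpy as np
import pytest

from esvland import CategoryScheme, LandCoverGrid, SIX_CLASS_SCHEME
from esvland.study import study_area_table, study_coefficients


@pytest.fixture(scope="session")
def scheme():
    return SIX_CLASS_SCHEME


@pytest.fixture(scope="session")
def two_class_scheme():
    return CategoryScheme(codes=(1, 2), names=("a", "b"), nodata_code=0)


@pytest.fixture(scope="session")
def coeffs():
    return study_coefficients()


@pytest.fixture(scope="session")
def areas_1980():
    return study_area_table(1980)


@pytest.fixture
def random_grid(scheme):
    """50×50 six-class grid, fixed seed."""
    rng = np.random.default_rng(42)
    values = rng.choice(scheme.codes, size=(50, 50))
    return LandCoverGrid(values=values, cell_size=30.0, scheme=scheme)
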