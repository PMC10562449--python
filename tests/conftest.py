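import numpy as np
import pytest

from resalloc import make_world, standard_config, deficit_config
from resalloc.grid import GridField


@pytest.fixture(scope="session")
def standard_world():
    """Small standard world (supply and demand balanced) for unit tests."""
    return make_world(
        standard_config(seed=7, nlat=10, nlon=10,
                        year_start=2008, year_end=2012, base_year=2010)
    )


@pytest.fixture(scope="session")
def deficit_world():
    """Small world with livestock-demand hotspots, to exercise trade."""
    return make_world(
        deficit_config(seed=7, nlat=10, nlon=10,
                       year_start=2009, year_end=2011, base_year=2010)
    )


def toy_field(values, res=0.5, lat0=0.0, lon0=0.0, year=2010, units="Mg/yr"):
    """Convenience constructor for hand-built rasters."""
    return GridField.from_origin(np.asarray(values, dtype=float),
                                 lat0, lon0, res, year=year, units=units)


@pytest.fixture
def field_factory():
    return toy_field
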