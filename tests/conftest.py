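import numpy as np
import pytest

from nitraqua.data_model import SampleTable, WellSample


def make_table(xy, z, land_use="mixed", climate="arid") -> SampleTable:
    """Build a SampleTable from coordinate and value arrays."""
    xy = np.asarray(xy, dtype=float)
    z = np.asarray(z, dtype=float)
    return SampleTable(
        tuple(
            WellSample(
                well_id=f"W{i:03d}",
                x=float(xy[i, 0]),
                y=float(xy[i, 1]),
                elev=300.0,
                climate=climate,
                land_use=land_use,
                season="spring",
                nitrate=float(z[i]),
            )
            for i in range(len(z))
        )
    )


@pytest.fixture
def table_factory():
    return make_table


@pytest.fixture
def random_table():
    """12 wells scattered over a 1 km square with moderate nitrate values."""
    rng = np.random.default_rng(12345)
    xy = rng.uniform(0.0, 1000.0, (12, 2))
    z = rng.uniform(10.0, 40.0, 12)
    return make_table(xy, z)
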