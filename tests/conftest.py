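import numpy as np
import pandas as pd
import pytest

from vegrisk import ScenarioConfig, generate_scenario
from vegrisk.grids import ClimateField


@pytest.fixture(scope="session")
def small_scenario():
    """One modest scenario shared by read-only tests."""
    cfg = ScenarioConfig(seed=11, n_species=60, extent=(0.0, 0.0, 600.0, 600.0))
    return generate_scenario(cfg)


@pytest.fixture()
def tiny_field():
    """Hand-built 2x2 field: values known per cell, 10-km cells at origin."""
    vals = np.array([[1.0, 2.0], [3.0, 4.0]])  # row 0 = south
    return ClimateField(vals, x0=0.0, y0=0.0, cell=10.0, variable="MAT")


@pytest.fixture()
def toy_records():
    """Five records containing two duplicated pairs (three unique keys)."""
    base = {
        "year": 1990, "month": 5, "recordedBy": "Collector A.",
        "basisOfRecord": "PreservedSpecimen", "outlier_flag": False,
        "cultivated_flag": False, "free_text": "",
    }
    rows = [
        {"species": "A", "decimalLongitude": 1.0, "decimalLatitude": 2.0, **base},
        {"species": "A", "decimalLongitude": 1.0, "decimalLatitude": 2.0, **base},
        {"species": "B", "decimalLongitude": 1.0, "decimalLatitude": 2.0, **base},
        {"species": "B", "decimalLongitude": 1.0, "decimalLatitude": 2.0, **base},
        {"species": "C", "decimalLongitude": 9.0, "decimalLatitude": 9.0, **base},
    ]
    return pd.DataFrame(rows)
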