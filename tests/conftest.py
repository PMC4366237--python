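import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import firecount as fc

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")

# the reference maximum-temperature moments are internally inconsistent by
# construction (mean above max); the generator warns every time
warnings.filterwarnings(
    "ignore", message="configured mean for 'tmax'", category=UserWarning
)


@pytest.fixture(scope="session")
def tiny_panel():
    """Hand-built 2-county, 6-observation panel."""
    df = pd.DataFrame({
        "county": ["a", "a", "a", "b", "b", "b"],
        "year": [2000, 2000, 2001, 2000, 2000, 2001],
        "month": [1, 2, 1, 1, 2, 1],
        "fire_count": [0, 3, 1, 5, 0, 2],
        "tmax": [15.0, 16.0, 14.0, 18.0, 17.0, 15.5],
        "tmean": [10.0, 11.0, 9.0, 12.0, 11.5, 10.5],
        "humidity": [70.0, 80.0, 75.0, 90.0, 65.0, 72.0],
        "wind_mean": [1.5, 1.2, 1.8, 1.1, 2.0, 1.4],
        "wind_max": [5.0, 6.0, 7.0, 4.0, 8.0, 5.5],
        "precipitation": [30.0, 20.0, 45.0, 10.0, 55.0, 25.0],
        "evaporation": [50.0, 60.0, 70.0, 80.0, 40.0, 55.0],
    })
    return fc.PanelDataset(df)


@pytest.fixture(scope="session")
def reference_panel():
    """Panel generated from the NB-mixed preset at the reference scale
    (12 counties x 12 years x 4 months)."""
    sc = fc.reference_scenarios()["nb-mixed"]
    return fc.generate_panel(sc, seed=42)


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced-size helper used where the full 576-row panel is overkill."""
    sc = fc.reference_scenarios()["nb-mixed"]
    return dataclasses.replace(sc, n_counties=6, n_years=4)


@pytest.fixture(scope="session")
def nb_mixed_fit(reference_panel):
    """NB-mixed fit on the reference panel, shared across tests."""
    sc = fc.reference_scenarios()["nb-mixed"]
    res = fc.fit(sc.spec, reference_panel, seed=0)
    assert res.converged
    return res
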