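import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from brasspf import AgeGroupGrid, FertilitySchedule, ParitySchedule
from brasspf.datasets import PROVINCES, load_province

# 3-decimal reference cells for the packaged province datasets:
# cumulative fertility, P/F ratio, P3/F3-adjusted ASFR, adjusted TFR.
REFERENCE_TABLES = {
    "bihar": {
        "cum_fertility": [0.275, 1.485, 2.640, 3.530, 4.025, 4.285, 4.360],
        "pf_ratio": [5.345, 2.357, 1.481, 1.428, 1.389, 1.449, 1.479],
        "adjusted_asfr": [0.407, 1.792, 1.711, 1.318, 0.733, 0.385, 0.111],
        "tfr_adj": 6.457,
    },
    "uttar_pradesh": {
        "cum_fertility": [0.200, 1.440, 2.795, 3.785, 4.360, 4.670, 4.785],
        "pf_ratio": [8.055, 1.894, 1.442, 1.415, 1.379, 1.435, 1.432],
        "adjusted_asfr": [0.288, 1.788, 1.954, 1.427, 0.829, 0.447, 0.166],
        "tfr_adj": 6.899,
    },
    "goa": {
        "cum_fertility": [0.025, 0.320, 0.870, 1.240, 1.380, 1.415, 1.420],
        "pf_ratio": [56.000, 6.981, 2.834, 2.213, 2.378, 2.873, 3.137],
        "adjusted_asfr": [0.071, 0.836, 1.559, 1.049, 0.397, 0.099, 0.014],
        "tfr_adj": 4.025,
    },
    "madhya_pradesh": {
        "cum_fertility": [0.440, 1.815, 2.885, 3.515, 3.830, 3.970, 3.995],
        "pf_ratio": [3.557, 1.556, 1.416, 1.430, 1.505, 1.547, 1.659],
        "adjusted_asfr": [0.623, 1.947, 1.515, 0.892, 0.446, 0.198, 0.035],
        "tfr_adj": 5.658,
    },
    "tamil_nadu": {
        "cum_fertility": [0.155, 1.050, 1.670, 1.895, 1.950, 1.965, 1.970],
        "pf_ratio": [9.374, 1.882, 1.557, 1.587, 1.808, 2.162, 2.485],
        "adjusted_asfr": [0.241, 1.394, 0.966, 0.350, 0.086, 0.023, 0.008],
        "tfr_adj": 3.068,
    },
}

assert set(REFERENCE_TABLES) == set(PROVINCES)


@pytest.fixture(scope="session")
def provinces():
    return {name: load_province(name) for name in PROVINCES}


@pytest.fixture(scope="session")
def bihar(provinces):
    return provinces["bihar"]


@pytest.fixture
def uniform_schedule():
    """Flat interval schedule with TFR 7 on the default grid."""
    return FertilitySchedule(f=np.ones(7))


@pytest.fixture
def unit_parity():
    grid = AgeGroupGrid()
    return ParitySchedule(grid, np.cumsum(np.ones(7)))
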