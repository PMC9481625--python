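import numpy as np
import pandas as pd
import pytest

from alleleniche import geo, synthetic


@pytest.fixture(scope="session")
def world():
    """The standard study-condition synthetic world (100x100, 40+57 records)."""
    return synthetic.make_default_world(seed=1)


@pytest.fixture(scope="session")
def small_world():
    """A small, cheap world for fit-heavy tests: 40x40, two variables."""
    return synthetic.make_world(
        seed=7, n_rows=40, n_cols=40, var_names=["BIO10", "BIO13"],
        smoothing_scale=3.0, inter_var_correlation=0.3,
        niches=synthetic.default_niches(),
        n_per_allele={"HbS": 30, "HbF": 30}, min_distance_km=0.0,
        future_shifts={"BIO10": 2.0})


@pytest.fixture
def tiny_stack():
    """3x3 two-layer stack with one NoData cell in layer 2."""
    layer1 = np.arange(9, dtype=float).reshape(3, 3)
    layer2 = layer1 * 2 + 1
    layer2[1, 1] = np.nan
    data = np.stack([layer1, layer2])
    return geo.ClimateStack(["a", "b"], data, xllcorner=0.0, yllcorner=0.0,
                            cellsize=1.0)


def make_occurrences(points, allele="X"):
    """points: [(lon, lat), ...] or [(lon, lat, allele), ...]"""
    rows = []
    for p in points:
        if len(p) == 2:
            rows.append({"longitude": p[0], "latitude": p[1], "allele": allele})
        else:
            rows.append({"longitude": p[0], "latitude": p[1], "allele": p[2]})
    return geo.OccurrenceSet(pd.DataFrame(rows))
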