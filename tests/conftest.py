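import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from florahom.checklists import PresenceData
from florahom.phylo import parse_newick

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

TOY_NEWICK = "((s1:1,s2:1):1,(s3:1,s4:1):1);"


@pytest.fixture
def toy_tree():
    return parse_newick(TOY_NEWICK)


@pytest.fixture
def toy_regions():
    return pd.DataFrame(
        {
            "region_id": ["A", "B", "C"],
            "name": ["Alpha", "Beta", "Gamma"],
            "country_code": ["X", "X", "Y"],
            "centroid_lon": [0.0, 10.0, 120.0],
            "centroid_lat": [0.0, 5.0, -30.0],
            "area_km2": [1000.0, 2000.0, 500.0],
            "is_island": [False, False, True],
        }
    )


@pytest.fixture
def toy_presence():
    # regions A, B; species s1..s4 on the toy tree
    native = np.array(
        [
            [1, 1, 0, 0],  # A: s1, s2
            [0, 1, 1, 0],  # B: s2, s3
        ],
        dtype=bool,
    )
    naturalized = np.array(
        [
            [0, 0, 1, 0],  # s3 naturalized in A (native to B)
            [1, 0, 0, 1],  # s1 (native to A) and s4 (native to neither) in B
        ],
        dtype=bool,
    )
    return PresenceData(
        regions=["A", "B"],
        species=["s1", "s2", "s3", "s4"],
        native=native,
        naturalized=naturalized,
    )


def random_presence(rng, n_regions=8, n_species=30):
    """Random consistent presence data: native cells, then naturalized cells
    drawn only where the species is not native."""
    native = rng.random((n_regions, n_species)) < 0.35
    for i in range(n_regions):  # every region needs natives
        if not native[i].any():
            native[i, rng.integers(n_species)] = True
    naturalized = (rng.random((n_regions, n_species)) < 0.15) & ~native
    keep = (native | naturalized).any(axis=0)
    return PresenceData(
        regions=[f"r{i}" for i in range(n_regions)],
        species=[f"s{j:03d}" for j in np.flatnonzero(keep)],
        native=native[:, keep],
        naturalized=naturalized[:, keep],
    )
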