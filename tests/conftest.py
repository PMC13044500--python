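import numpy as np
import pandas as pd
import pytest

import habnet as hn


@pytest.fixture(scope="session")
def small_config():
    """A compact synthetic survey used by several suites (cheap to generate)."""
    return hn.GeneratorConfig(n_landscapes=6, n_species=40, effort=20.0, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return hn.generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_analysis(small_dataset):
    """Excluded locations + per-landscape networks for the small survey."""
    locations = hn.exclude_settlement_locations(small_dataset.locations)
    networks = hn.build_all_networks(locations, small_dataset.bees)
    return locations, networks


@pytest.fixture()
def toy_locations():
    """Four locations in one landscape, two habitats, fully specified covers."""
    return pd.DataFrame(
        {
            "location_id": ["A1", "A2", "A3", "A4"],
            "landscape_id": ["LX"] * 4,
            "arable": [1.0, 0.8, 0.0, 0.1],
            "forest": [0.0, 0.2, 1.0, 0.9],
            "dominant_habitat": ["arable", "arable", "forest", "forest"],
            "excluded": [False] * 4,
        }
    )


@pytest.fixture()
def toy_bees():
    return pd.DataFrame(
        {
            "location_id": ["A1", "A1", "A2", "A3", "A4"],
            "species": ["sp1", "sp2", "sp1", "sp3", "sp2"],
            "abundance": [2, 3, 1, 4, 5],
        }
    )


@pytest.fixture()
def toy_landscapes():
    return pd.DataFrame(
        {
            "landscape_id": ["LX"],
            "arable": [0.5],
            "forest": [0.5],
            "shannon_h": [float(np.log(2))],
        }
    )
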