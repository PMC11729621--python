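import numpy as np
import pytest

import hetmct as hm

LEVELS = ["V1", "V2", "V3", "V4", "V5"]
LOCATIONS = ["Ba", "He", "Ho"]


@pytest.fixture(scope="session")
def myco_stats():
    return hm.mycotoxin_summary()


@pytest.fixture(scope="session")
def myco_data():
    return hm.mycotoxin_dataset(seed=0)


@pytest.fixture(scope="session")
def C12():
    """The 12 x 15 many-to-one-by-location contrast matrix."""
    return hm.dunnett_by_stratum(3, 5, 1, level_names=LEVELS, stratum_names=LOCATIONS)


def random_layout(rng, H=None, max_treatments=3, max_n=7):
    """Random variance-grouped layout with raw data for property tests."""
    H = H or rng.integers(1, 4)
    treatments, groups, obs = [], [], []
    for h in range(H):
        n_trt = rng.integers(1, max_treatments + 1)
        if h == H - 1 and len(treatments) + n_trt < 2:
            n_trt = 2
        for i in range(n_trt):
            treatments.append(f"g{h}t{i}")
            groups.append(f"g{h}")
            n = int(rng.integers(2, max_n))
            obs.append(rng.normal(rng.normal(0, 5), 1 + h, size=n))
    layout = hm.VarianceLayout(treatments, groups, [len(x) for x in obs])
    return hm.Dataset(layout=layout, observations=tuple(obs))
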