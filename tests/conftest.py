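import numpy as np
import pandas as pd
import pytest

from dynconn import CohortConfig, GroupDesign, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Two groups x 10 subjects, 20 regions, default planted dynamics."""
    cfg = CohortConfig(n_per_group=10, groups=("HC", "AX"), n_regions=20,
                       seed=42)
    return generate_cohort(cfg)


@pytest.fixture
def toy_atlas():
    """5 regions across 2 networks for hand-countable summaries."""
    return pd.DataFrame({
        "region_id": [0, 1, 2, 3, 4],
        "label": ["A_one", "A_two", "A_dlPFC", "B_one", "B_two"],
        "network": ["NetA", "NetA", "NetA", "NetB", "NetB"],
    })


def make_design(n_a, n_b, seed=0, groups=("HC", "AX")):
    rng = np.random.default_rng(seed)
    n = n_a + n_b
    return GroupDesign(
        subject_id=[f"s{i}" for i in range(n)],
        group=np.array([groups[0]] * n_a + [groups[1]] * n_b),
        age=rng.normal(30, 8, n),
        sex=rng.integers(0, 2, n).astype(float),
    )
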