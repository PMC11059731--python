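import numpy as np
import pandas as pd
import pytest

import compng as c


@pytest.fixture(scope="session")
def synth():
    """Default-scale synthetic dataset (81 samples x 661 features)."""
    return c.generate_dataset(c.SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_config():
    """Reduced-scale generator settings for fast tests."""
    return c.SimConfig(n_samples=30, n_classes=2, n_orders=4, n_genera=10,
                       n_asvs=40, depth_log_mean=float(np.log(5000.0)),
                       seed=11)


@pytest.fixture(scope="session")
def small_synth(small_config):
    return c.generate_dataset(small_config)


@pytest.fixture
def toy_counts():
    """4 samples x 3 features with hand-checkable values."""
    df = pd.DataFrame(
        [[2, 1, 4], [0, 1, 2], [0, 1, 1], [0, 1, 3]],
        index=["s1", "s2", "s3", "s4"], columns=["A", "B", "C"])
    return c.CountTable(df)
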