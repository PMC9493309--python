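import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from micronet import AbundanceTable, CommunitySpec, generate_counts

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def tiny_table():
    """3 taxa x 4 samples with two groups."""
    counts = pd.DataFrame(
        [[10, 0, 5, 7], [0, 3, 8, 1], [2, 2, 2, 2]],
        index=["t1", "t2", "t3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    groups = pd.Series(["A", "A", "B", "B"], index=counts.columns)
    return AbundanceTable(counts, groups)


@pytest.fixture(scope="session")
def block_table():
    """Block-correlated synthetic table: 3 modules of 20 + 60 background,
    30 samples — the standard recovery setting used across tests."""
    spec = CommunitySpec(
        n_samples_per_group=30, n_groups=1, n_taxa=120, n_modules=3,
        module_sizes=[20, 20, 20], within_module_corr=0.75, seed=11,
    )
    return generate_counts(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
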