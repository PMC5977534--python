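import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ffpeseq import CountMatrix, SimConfig, simulate_study

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A desk-scale study design: full factorial grid, fast to simulate."""
    return SimConfig(
        n_genes=800,
        depth_total_reads=400_000,
        coverage_reads=20_000,
        coverage_n_transcripts=50,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_study(small_config)


@pytest.fixture()
def tiny_counts() -> CountMatrix:
    counts = pd.DataFrame(
        {"s1": [10, 30, 60], "s2": [0, 5, 15]},
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
        dtype=np.int64,
    )
    return CountMatrix(counts=counts, library_sizes=pd.Series({"s1": 100, "s2": 40}))
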