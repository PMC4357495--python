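import numpy as np
import pytest

from snpig import ScanConfig, SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """30-SNP simulated dataset reused by scan/network/pipeline tests."""
    return simulate_dataset(
        SimulationConfig(model_id=4, maf_disease=0.25, heritability=0.02,
                         n_cases=300, n_controls=300, n_snps=30, seed=11)
    )


@pytest.fixture
def loose_scan_config():
    return ScanConfig(alpha=0.005)


def random_contingency(rng, n_max=60):
    """Random 3x3x2 count table with both phenotype classes present."""
    while True:
        counts = rng.integers(0, n_max, size=(3, 3, 2))
        if counts[:, :, 0].sum() > 0 and counts[:, :, 1].sum() > 0:
            return counts
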