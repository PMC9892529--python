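import numpy as np
import pandas as pd
import pytest

from lipomr.synthetic import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """Two modest cohorts, 5 causal genes: shared by several test modules."""
    cfg = SimulationConfig(
        cohorts=("LL", "RS"), samples_per_cohort=(600, 600),
        n_genes=150, n_causal=5, causal_beta=0.4,
    )
    return simulate_study(cfg, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_counts(rng):
    """20 genes x 6 samples with two strongly 'DE' genes and depth spread."""
    base = rng.integers(50, 2000, size=(20, 1))
    depth = np.array([1.0, 0.5, 2.0, 1.0, 1.5, 0.8])
    counts = (base * depth).astype(int) + rng.integers(0, 30, size=(20, 6))
    counts[0, :3] *= 8   # DE in half the samples
    counts[1, 3:] *= 6
    return pd.DataFrame(counts, index=[f"g{i}" for i in range(20)],
                        columns=[f"s{j}" for j in range(6)])
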