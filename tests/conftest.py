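import numpy as np
import pandas as pd
import pytest

from beclear import BatchAssignment, BetaMatrix, SimulationSpec, simulate_beta_matrix


@pytest.fixture
def small_matrix():
    """4 features x 6 samples with one missing entry."""
    rng = np.random.default_rng(1)
    values = rng.uniform(0.1, 0.9, (4, 6))
    df = pd.DataFrame(values, index=[f"g{i}" for i in range(4)],
                      columns=[f"s{j}" for j in range(6)])
    df.iloc[2, 3] = np.nan
    return BetaMatrix(df)


@pytest.fixture
def small_batches():
    return BatchAssignment.from_dict(
        {f"s{j}": ("A" if j < 3 else "B") for j in range(6)}
    )


@pytest.fixture(scope="session")
def benchmark_pristine():
    """One fixed 2000 x 96 pristine dataset shared by the slower tests."""
    spec = SimulationSpec(k=0.0, n_affected=0, seed=42)
    return simulate_beta_matrix(spec)
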