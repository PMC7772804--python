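import numpy as np
import pandas as pd
import pytest

from coxis import ExpressionMatrix, Scale
from coxis.simulate import SimulationConfig, simulate_cohort


@pytest.fixture
def small_counts() -> ExpressionMatrix:
    """3 genes x 2 samples, tiny counts."""
    df = pd.DataFrame(
        [[1, 4], [1, 4], [2, 8]],
        index=["CXCL9", "IL6", "GZMB"],
        columns=["s1", "s2"],
    )
    return ExpressionMatrix(values=df, scale=Scale.COUNTS)


@pytest.fixture
def random_log2(rng) -> ExpressionMatrix:
    """50 genes x 20 samples of random non-negative log2 expression."""
    genes = [f"G{i:03d}" for i in range(50)]
    samples = [f"s{i:02d}" for i in range(20)]
    vals = rng.uniform(0, 12, size=(50, 20))
    return ExpressionMatrix(
        values=pd.DataFrame(vals, index=genes, columns=samples), scale=Scale.LOG2
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter cohort shared across read-only tests."""
    return simulate_cohort(SimulationConfig(), seed=1234)


@pytest.fixture(scope="session")
def small_cohort():
    """A quicker cohort for pipeline smoke tests."""
    return simulate_cohort(
        SimulationConfig(n_samples=80, n_background_genes=100), seed=99
    )
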