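import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from clbso import ExpressionDataset, SyntheticSpec, generate_synthetic_expression

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tiny_dataset() -> ExpressionDataset:
    """30 samples x 12 genes, 2 strongly informative genes: fast wrapper runs."""
    ds, _ = generate_synthetic_expression(
        SyntheticSpec(n_samples=30, n_genes=12, n_informative=2, effect_size=3.0, seed=42)
    )
    return ds


@pytest.fixture(scope="session")
def tiny_truth():
    _, truth = generate_synthetic_expression(
        SyntheticSpec(n_samples=30, n_genes=12, n_informative=2, effect_size=3.0, seed=42)
    )
    return truth


@pytest.fixture
def small_rng():
    return np.random.default_rng(0)
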