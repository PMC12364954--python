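import numpy as np
import pandas as pd
import pytest

from cernet.core import ExpressionMatrix
from cernet.simulate import canonical_config, simulate_dataset


def make_matrix(rows: dict, classes: dict, n_per_group: int | None = None) -> ExpressionMatrix:
    """Build a small ExpressionMatrix from {feature: values} and {feature: class}."""
    values = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in rows.items()}).T
    n = values.shape[1]
    if n_per_group is None:
        n_per_group = n // 2
    sample_ids = [f"A{i+1}" for i in range(n_per_group)] + [
        f"B{i+1}" for i in range(n - n_per_group)
    ]
    values.columns = sample_ids
    groups = pd.Series(
        ["groupA"] * n_per_group + ["groupB"] * (n - n_per_group), index=sample_ids
    )
    return ExpressionMatrix(
        values=values,
        feature_class=pd.Series(classes),
        group_of_sample=groups,
    )


@pytest.fixture(scope="session")
def fixture_dataset():
    """Canonical simulated dataset: 6 samples, 60 background features, 5 triads."""
    return simulate_dataset(canonical_config(seed=7))


@pytest.fixture(scope="session")
def noise_free_triad():
    """Single planted triad with zero measurement noise (exact couplings)."""
    return simulate_dataset(canonical_config(seed=11, n_planted_triads=1, noise_sd=0.0))
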