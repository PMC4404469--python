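import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20150415)


@pytest.fixture
def random_quantities(rng):
    """Factory for random positive quantity matrices (genes x samples)."""

    def make(n_genes, n_samples, sd=0.6):
        logq = rng.normal(0.0, sd, size=(n_genes, n_samples))
        frame = pd.DataFrame(
            2.0 ** logq,
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
        return frame

    return make
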