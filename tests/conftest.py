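import numpy as np
import pytest

from fsnmm import DiagnosisLabels, SimulationConfig, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_class_labels():
    return DiagnosisLabels(labels=np.array(["HC"] * 4 + ["MD"] * 4))


@pytest.fixture
def small_dataset():
    """Default-structure dataset small enough for exhaustive checks."""
    return simulate(
        SimulationConfig(n_per_class=(8, 8, 8), d=16, subspace_dim=3, seed=7)
    )


@pytest.fixture
def clean_subspace_dataset():
    """Noise-free classes lying exactly in 2-dim linear subspaces."""
    return simulate(
        SimulationConfig(
            n_per_class=(10, 10),
            d=12,
            subspace_dim=2,
            noise_sd_features=0.0,
            class_sep=0.0,
            response_mode="continuous",
            seed=11,
        )
    )
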