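import warnings

import numpy as np
import pandas as pd
import pytest

from imfnet.data_model import CountMatrix, PhenotypeTable
from imfnet.simulate import ModuleSpec, SimConfig, default_config, generate_dataset

warnings.filterwarnings("ignore", message="divide by zero")


@pytest.fixture(scope="session")
def small_dataset():
    """A scaled-down dataset with the full planted structure (fast to analyze)."""
    config = default_config(7)
    from dataclasses import replace

    config = replace(config, n_genes=400, n_mirnas=60)
    return generate_dataset(config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_group_pheno():
    def make(n_per_group: int, seed: int = 0) -> PhenotypeTable:
        r = np.random.default_rng(seed)
        n = 2 * n_per_group
        return PhenotypeTable(
            pd.DataFrame(
                {
                    "sample_id": [f"s{i:02d}" for i in range(n)],
                    "imf_percent": np.round(r.uniform(1, 5, n), 2),
                    "gebv": np.round(r.normal(0, 0.5, n), 3),
                    "group": ["H"] * n_per_group + ["L"] * n_per_group,
                }
            )
        )

    return make


@pytest.fixture
def poisson_counts(rng):
    def make(n_features: int, n_samples: int, mean: float = 100.0, layer: str = "mRNA"):
        values = rng.poisson(mean, size=(n_features, n_samples))
        return CountMatrix(
            values,
            [f"f{i:03d}" for i in range(n_features)],
            [f"s{j:02d}" for j in range(n_samples)],
            layer,
        )

    return make
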