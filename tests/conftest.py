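import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from lncpath import (
    ExpressionMatrix,
    PlantedSet,
    SyntheticConfig,
    generate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A quick cohort with a strong planted signal for unit tests."""
    cfg = SyntheticConfig(
        n_samples=80,
        n_genes=400,
        planted_sets=(PlantedSet("PLANTED_PATHWAY", 20, 1.0, 1.0),),
        n_null_sets=12,
        null_set_size_range=(8, 30),
        noise_sd=0.5,
        seed=101,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_matrix(rng, n_genes=6, n_samples=5, log_transformed=False, prefix="G"):
    data = pd.DataFrame(
        rng.gamma(2.0, 3.0, size=(n_genes, n_samples)),
        index=[f"{prefix}{i}" for i in range(n_genes)],
        columns=[f"TCGA-XX-{i:04d}-01A" for i in range(n_samples)],
    )
    return ExpressionMatrix(data, cohort="TEST", log_transformed=log_transformed)
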