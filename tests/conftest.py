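import warnings

import numpy as np
import pandas as pd
import pytest

from mirti.datamodel import ExpressionMatrix
from mirti.simulate import (
    Reference,
    SyntheticConfig,
    make_reference,
    simulate_expression_cohort,
)


@pytest.fixture(autouse=True)
def _quiet_generator_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=UserWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_reference() -> Reference:
    """A compact deterministic reference shared by read-only tests."""
    return make_reference(SyntheticConfig(seed=5, n_genes=60, n_families=8))


@pytest.fixture(scope="session")
def small_cohort():
    """(config, reference, mirna counts, mrna, annotation) on a small scale."""
    config = SyntheticConfig(
        seed=5,
        n_genes=60,
        n_families=8,
        samples_per_subtype={"basal-like": 30, "HER2": 20},
        background_clusters=10,
        decoy_clusters=5,
    )
    reference = make_reference(config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mirna, mrna, annotation = simulate_expression_cohort(config, reference)
    return config, reference, mirna, mrna, annotation


def make_matrix(values, entity_kind="mrna", scale="a_value", prefix="e", samples=None):
    values = np.asarray(values, dtype=float)
    index = [f"{prefix}{i}" for i in range(values.shape[0])]
    columns = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=index, columns=columns), entity_kind, scale)
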