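import numpy as np
import pandas as pd
import pytest

from respifuse import CohortSpec, FeatureTable, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Small but structurally complete cohort shared across tests."""
    return generate_cohort(CohortSpec(n_pos=20, n_neg=8, seed=11,
                                      duration=4.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_table(values, labels, prefix="f"):
    values = np.asarray(values, dtype=float)
    ids = [f"s{i:03d}" for i in range(values.shape[0])]
    cols = [f"{prefix}{j}" for j in range(values.shape[1])]
    return FeatureTable(pd.DataFrame(values, index=ids, columns=cols), labels)


@pytest.fixture()
def table_factory():
    return make_table
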