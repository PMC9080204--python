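import numpy as np
import pandas as pd
import pytest

from lggpc import (
    ExpressionMatrix,
    SampleSheet,
    SimulationParams,
    de_test,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def cohort():
    """One default-parameter synthetic cohort, shared across tests."""
    return simulate_cohort(SimulationParams(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """A lighter cohort for tests that only need structure, not power."""
    return simulate_cohort(SimulationParams(seed=7, n_features=900))


@pytest.fixture(scope="session")
def de_results(cohort):
    """The three subtype contrasts on the default cohort."""
    protein, _, samples, _, _ = cohort
    return (
        de_test(protein, samples, "TYPE_I", "TYPE_II"),
        de_test(protein, samples, "TYPE_I", "TYPE_III"),
        de_test(protein, samples, "TYPE_II", "TYPE_III"),
    )


@pytest.fixture()
def tiny_matrix():
    rng = np.random.default_rng(3)
    data = pd.DataFrame(
        rng.normal(8, 1, size=(6, 8)),
        index=[f"F{i}" for i in range(6)],
        columns=[f"S{i}" for i in range(8)],
    )
    return ExpressionMatrix(data, "log2")


@pytest.fixture()
def two_group_sheet():
    ids = [f"S{i}" for i in range(8)]
    subtypes = ["TYPE_I"] * 4 + ["TYPE_II"] * 4
    return SampleSheet(
        pd.DataFrame({"subtype": subtypes}, index=pd.Index(ids, name="sample_id"))
    )
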