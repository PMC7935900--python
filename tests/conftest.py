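import warnings

import numpy as np
import pandas as pd
import pytest

from methex import CohortConfig, generate_bulk_cohort

warnings.filterwarnings("ignore", message="divide by zero")


@pytest.fixture(scope="session")
def bundle():
    """A mid-sized cohort with planted structure, shared across tests."""
    return generate_bulk_cohort(CohortConfig(n_samples=150, seed=42, n_null_metabolites=30))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def tiny_expr():
    """3 genes x 4 samples log2 matrix."""
    return pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [2.0, 2.0, 2.0, 2.0], [5.0, 1.0, 0.5, 3.0]],
        index=["G1", "G2", "G3"],
        columns=["S1", "S2", "S3", "S4"],
    )


@pytest.fixture()
def surv_no_ties():
    """8 subjects, distinct event times, binary covariate."""
    time = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
    event = [1, 1, 1, 0, 1, 1, 0, 1]
    x = [1, 1, 0, 1, 0, 1, 0, 0]
    idx = [f"P{i}" for i in range(8)]
    surv = pd.DataFrame({"time": time, "event": event}, index=idx)
    cov = pd.Series(x, index=idx, name="x", dtype=float)
    return surv, cov
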