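import numpy as np
import pandas as pd
import pytest

from icikit.io_core import ClinicalTable, ExpressionMatrix
from icikit.synthetic import simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """100-sample default-structure cohort shared by read-only tests."""
    return simulate_cohort(n_samples=100, n_genes=300, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_expr(values: np.ndarray, unit: str = "LOG2TPM", prefix: str = "g") -> ExpressionMatrix:
    genes = [f"{prefix}{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), unit=unit)


def make_clinical(times, events, index=None) -> ClinicalTable:
    times = np.asarray(times, dtype=float)
    if index is None:
        index = [f"s{i}" for i in range(len(times))]
    return ClinicalTable(
        pd.DataFrame({"os_time": times, "os_event": np.asarray(events, dtype=int)}, index=index)
    )
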