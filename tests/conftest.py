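import numpy as np
import pandas as pd
import pytest

from hypro import ModelDesign, default_truth, simulate_counts
from hypro.matrix import CountMatrix


@pytest.fixture(scope="session")
def small_design() -> ModelDesign:
    return ModelDesign(n_genes=400)


@pytest.fixture(scope="session")
def small_dataset(small_design):
    truth = default_truth(
        small_design, seed=11, n_hdeg=30, n_deg=40, n_shared=20
    )
    cm, truth = simulate_counts(small_design, truth, seed=11)
    return cm, truth


@pytest.fixture()
def tiny_counts() -> CountMatrix:
    """Hand-sized 4-gene, 4-sample count matrix."""
    genes = ["g1", "g2", "g3", "g4"]
    counts = pd.DataFrame(
        {
            "s1": [10, 30, 0, 5],
            "s2": [12, 28, 1, 6],
            "s3": [40, 10, 2, 5],
            "s4": [38, 12, 0, 7],
        },
        index=genes,
    )
    lengths = pd.Series([1000, 1000, 2000, 500], index=genes)
    samples = pd.DataFrame(
        {
            "stage": ["a", "a", "b", "b"],
            "condition": ["atm", "atm", "atm", "atm"],
            "replicate": [1, 2, 1, 2],
        },
        index=counts.columns,
    )
    return CountMatrix(counts=counts, lengths=lengths, samples=samples)


@pytest.fixture(scope="session")
def survival_cohort_six() -> pd.DataFrame:
    """Six-patient fixture with hand-computed log-rank quantities."""
    return pd.DataFrame(
        {
            "time": [1, 3, 5, 2, 4, 6],
            "event": [1, 1, 0, 1, 1, 1],
            "expression": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        }
    )
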