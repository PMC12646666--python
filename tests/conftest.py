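import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("fixed", derandomize=True, deadline=None)
settings.load_profile("fixed")

from stabsig import (CountMatrix, NormalizedMatrix, SimulationConfig, StudyDesign,
                     simulate_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_counts():
    """4 genes x 3 samples with distinct, hand-checkable values."""
    return CountMatrix(
        ["g1", "g2", "g3", "g4"], ["s1", "s2", "s3"],
        np.array([[5, 10, 20], [1, 2, 4], [100, 200, 400], [7, 14, 28]]),
    )


@pytest.fixture
def small_meta():
    return pd.DataFrame({
        "sample_id": ["s1", "s2", "s3"],
        "study": ["A", "A", "A"],
        "arm": ["treated", "treated", "placebo"],
        "response": ["R", "NR", "unknown"],
        "batch": ["b0", "b0", "b0"],
    })


@pytest.fixture(scope="session")
def planted_cohort():
    """Small two-study cohort with a strong planted signal (session-cached)."""
    cfg = SimulationConfig(
        n_genes=200, n_signal_pos=5, n_signal_neg=5, effect_log2fc=2.0,
        placebo_progression_genes=10,
        studies={
            "A": StudyDesign(n_treated_R=15, n_treated_NR=15, n_placebo=10),
            "B": StudyDesign(n_treated_R=10, n_treated_NR=10),
        },
        seed=11,
    )
    return simulate_cohort(cfg)


def as_normalized(values, gene_ids=None, sample_ids=None):
    values = np.asarray(values, dtype=float)
    g, s = values.shape
    return NormalizedMatrix(
        gene_ids or [f"g{i}" for i in range(g)],
        sample_ids or [f"s{j}" for j in range(s)],
        values,
    )
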