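import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from tmetargets.io import ExpressionMatrix
from tmetargets.simulate import (
    GeneSpec,
    ResponderSimConfig,
    SimulationConfig,
    simulate_pan_cancer,
    simulate_responder_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix():
    """3-gene x 4-sample cohort with one missing cell."""
    data = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0], [0.5, np.nan, 1.5, 1.0]],
        index=["CD3E", "GENEA", "GENEB"],
        columns=["S1", "S2", "S3", "S4"],
    )
    return ExpressionMatrix(cancer_type="TESTCT", data=data)


@pytest.fixture
def planted_config():
    """Small two-factor simulation with a marker, a PD-1-axis gene, signal and nulls."""
    specs = [
        GeneSpec("CD3E", 1.0, 0.0, 0.0),
        GeneSpec("PDCD1", 0.8, 0.55, 0.3),
        GeneSpec("CTLA4", 0.7, 0.35, 0.5),
        GeneSpec("SIGNAL", 0.9, 0.0, 0.2),
        GeneSpec("SHARED", 0.9, 0.55, 0.2),
    ] + [GeneSpec(f"NULL{i:03d}", 0.0, 0.0, 1.0) for i in range(20)]
    return SimulationConfig(
        gene_specs=specs, n_cancer_types=4, n_samples_per_type=300, seed=11
    )


@pytest.fixture
def planted_cohorts(planted_config):
    return simulate_pan_cancer(planted_config)


@pytest.fixture
def responder_cohort():
    return simulate_responder_cohort(ResponderSimConfig(seed=42))
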