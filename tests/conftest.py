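import numpy as np
import pandas as pd
import pytest

from saltscan import SimulationConfig, gen_cohort


@pytest.fixture(scope="session")
def null_cohort():
    """Medium cohort with no genetic effect on BP (scan calibration input)."""
    config = SimulationConfig(n_subjects=800, n_variants=60, maf=0.3,
                              beta_G=0.0, beta_GE=0.0, seed=11)
    cohort, genotypes = gen_cohort(config)
    from saltscan import prepare_cohort
    return prepare_cohort(cohort), genotypes


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def worked_dataset():
    """Tiny hand-checkable dataset for the closed-form LRT oracle."""
    G = np.array([0, 1, 2, 0, 1, 2, 0, 1], dtype=float)
    E = np.array([120.0, 150.0, 180.0, 200.0, 130.0, 170.0, 160.0, 140.0])
    bp = np.array([118.0, 131.0, 146.0, 125.0, 129.0, 152.0, 121.0, 127.0])
    return G, E, bp
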