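import numpy as np
import pytest

from contrasurv.data import SurvivalOutcome
from contrasurv.simulate import SimulationConfig, generate_cohort

CLINICAL_SCHEMA = {"age": "continuous", "sex": "categorical",
                   "histology": "categorical"}


@pytest.fixture(scope="session")
def small_cohort():
    """120 patients, moderate censoring; shared by pipeline-level tests."""
    return generate_cohort(SimulationConfig(
        n_patients=120, seed=11, censoring_rate_target=0.6,
        n_mutation_genes=40, n_tiles_per_patient_range=(5, 12), tile_dim=8))


@pytest.fixture(scope="session")
def schema():
    return dict(CLINICAL_SCHEMA)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_outcomes(rng, n, event_prob=0.6, with_ties=False):
    t = rng.exponential(1.0, n)
    if with_ties and n >= 4:
        t = np.round(t, 1) + 0.05
    e = (rng.uniform(size=n) < event_prob).astype(int)
    if e.sum() == 0:
        e[int(rng.integers(n))] = 1
    return SurvivalOutcome(t, e)
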