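import numpy as np
import pytest

import femrisk as fr


@pytest.fixture(scope="session")
def fall_model():
    return fr.FallStochasticModel()


@pytest.fixture(scope="session")
def constants():
    return fr.FixedConstants()


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic validation cohort (98 subjects, fixed seed)."""
    config = fr.CohortGeneratorConfig()
    subjects, surfaces, labels = fr.generate_cohort(config, seed=11)
    return subjects, surfaces, labels


@pytest.fixture(scope="session")
def cohort_arf0(cohort, fall_model):
    """ARF0 of the session cohort at the verified default settings (N=10^4, M=33)."""
    subjects, surfaces, _ = cohort
    results = fr.run_cohort(subjects, surfaces, fall_model, N=10_000, seed=12)
    return np.array([r.ARF0 for r in results])
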