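import numpy as np
import pytest

from lipidstrat import simulate as sim


@pytest.fixture(scope="session")
def ldl_model():
    return sim.default_ldl_model()


@pytest.fixture(scope="session")
def tg_model():
    return sim.default_tg_model()


@pytest.fixture(scope="session")
def reference(ldl_model, tg_model):
    return sim.generate_reference_population(
        500, ldl_model, tg_model, seed=11
    )


@pytest.fixture(scope="session")
def cohort_spec():
    return sim.default_cohort_spec(seed=11)


@pytest.fixture(scope="session")
def cohort(cohort_spec, reference):
    return sim.generate_cohort(cohort_spec, reference)


@pytest.fixture(scope="session")
def ultrasound_records(cohort, cohort_spec):
    return sim.generate_ultrasound(cohort, cohort_spec, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
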