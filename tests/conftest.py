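import numpy as np
import pytest

from breathloop import default_subject
from breathloop.experiments import report, run_arms
from breathloop.physiology import CohortSpec, generate_cohort, simulate


@pytest.fixture()
def subject():
    """Calibrated cohort-mean virtual subject."""
    return default_subject()


@pytest.fixture(scope="session")
def arms_result():
    """Four-arm protocol run on the default subject (shared: ~3 s)."""
    return run_arms(default_subject())


@pytest.fixture(scope="session")
def untreated_run():
    """10 driver cycles of cardiac-output alternation, no dosing."""
    return simulate(default_subject(), "untreated", n_cycles=10)


@pytest.fixture(scope="session")
def cohort_study():
    """Default seeded 12-subject cohort through the full protocol
    (shared across tests: the expensive fixture, ~40 s)."""
    cohort = generate_cohort(CohortSpec())
    metrics = [run_arms(s).metrics for s in cohort]
    return cohort, metrics, report(metrics)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
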