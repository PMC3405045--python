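import warnings

import pytest

from billheat.model_selection import aggregate_steps
from billheat.synthetic import CohortConfig, generate_cohort, generate_experiment

# statsmodels mixed models routinely warn about boundary variance estimates
# on candidate sets; the fits themselves are checked against oracles.
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def cohort():
    """Default 18-bird cohort (9 per subspecies), seed 0."""
    return generate_cohort(CohortConfig(seed=0))


@pytest.fixture(scope="session")
def observations(cohort):
    """Default chamber experiment for the default cohort."""
    return generate_experiment(cohort, seed=1)


@pytest.fixture(scope="session")
def step_data(observations):
    """Per-(bird x ambient step) means, the default modelling unit."""
    return aggregate_steps(observations)
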