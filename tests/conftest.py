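import numpy as np
import pytest

from suidbayes.datasets import load_validation_fixture
from suidbayes.onset import OnsetIncidenceModel
from suidbayes.synthetic import MarginalSpec, generate_replicate_cohort


@pytest.fixture(scope="session")
def replicate_cohort():
    return generate_replicate_cohort(MarginalSpec.default(), seed=1)


@pytest.fixture(scope="session")
def validation_cases():
    return load_validation_fixture()


@pytest.fixture(scope="session")
def onset_model(replicate_cohort):
    return OnsetIncidenceModel().fit_cohort(replicate_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
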