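import numpy as np
import pytest

from mitovo2 import BiLstmSegmenter
from mitovo2.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def train_cohort():
    """20-subject labeled cohort used to train the detector."""
    return generate_cohort(CohortConfig(n_subjects=20, seed=7))


@pytest.fixture(scope="session")
def trained_model(train_cohort):
    """Detector trained once per session with the tuned hyperparameters."""
    traces = [c[0] for c in train_cohort]
    labels = [c[1] for c in train_cohort]
    return BiLstmSegmenter(seed=0).fit(traces, labels)


@pytest.fixture(scope="session")
def validation_cohort():
    """Independent 30-subject cohort for held-out evaluation."""
    return generate_cohort(CohortConfig(n_subjects=30, seed=1007))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
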