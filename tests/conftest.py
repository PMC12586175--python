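import numpy as np
import pytest

from pfcdev.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Two-subject, three-session cohort small enough for fast unit tests."""
    spec = CohortSpec(
        n_subjects=2,
        ages_months=[[46, 52, 58, 64], [46, 52, 58, 64]],
        mid_adolescence_month=[56.0, 59.0],
        seed=7,
        trials_per_session=40,
        n_distractor_subjects=1,
    )
    spec.neuron_spec.n_neurons_per_session = 6
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
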