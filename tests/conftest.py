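import warnings

import hypothesis
import pytest

from refsig import SyntheticSpec, generate_dataset_family

hypothesis.settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("default")

# scikit-learn convergence chatter is expected on tiny folds
warnings.filterwarnings("ignore", category=UserWarning)


SMALL_SPEC = SyntheticSpec(
    n_control=15,
    n_case=15,
    n_features=60,
    n_signal=6,
    log2_fold_change=3.0,
    dispersion=0.3,
    base_mean=50.0,
    trim_lengths=(30, 50, 50),
    n_duplicated_matches=2,
    dropout_signal=2,
    batch_log_shift=0.3,
    seed=7,
)


@pytest.fixture(scope="session")
def small_family():
    """A compact linked family: 1 discovery + 2 testing datasets,
    6 planted sequences (2 duplicated, 2 dropped per testing dataset)."""
    return generate_dataset_family(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_spec():
    return SMALL_SPEC
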