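import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from screensim import (
    SyntheticReviewSpec,
    TrainingProtocol,
    generate_review_dataset,
    run_training_protocol,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def separable_spec():
    """A cleanly separable synthetic review: high topic separation."""
    return SyntheticReviewSpec(n_records=2000, topic_separation=4.0, seed=42)


@pytest.fixture(scope="session")
def separable_dataset(separable_spec):
    return generate_review_dataset(separable_spec)


@pytest.fixture(scope="session")
def separable_run(separable_dataset):
    """Training protocol + predictions on the separable corpus."""
    return run_training_protocol(
        separable_dataset, TrainingProtocol(), order_seed=7
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A small mixed-difficulty dataset for IO and workflow tests."""
    spec = SyntheticReviewSpec(
        n_records=400,
        topic_separation=2.0,
        ta_inclusion_rate=0.15,
        final_inclusion_rate=0.05,
        seed=7,
    )
    return generate_review_dataset(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
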