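import numpy as np
import pytest

from meddistill.data import Preprocessor
from meddistill.models import build_student
from meddistill.synthetic import SyntheticSpec, generate_dataset
from meddistill.training import TrainConfig, train_student


def small_train_config(**overrides) -> TrainConfig:
    """Desk-scale training defaults shared by the heavier tests.

    Validation ACC is monitored: on easily separable fixtures AUC saturates
    immediately and the ties-to-earlier rule would return an undertrained
    checkpoint.
    """
    base = dict(temperature=2.0, alpha=0.2, epochs=8, batch_size=64,
                milestones=(), target_side=28, patience=100, seed=0,
                monitor="val_acc")
    base.update(overrides)
    return TrainConfig(**base)


EASY_SPEC = SyntheticSpec("multiclass", 4, n_train=400, n_val=80, n_test=80,
                          noise_sigma=20.0, seed=11)


@pytest.fixture(scope="session")
def easy_mc4_bundle():
    """Small, well-separated 4-class problem; trains in seconds."""
    return generate_dataset(EASY_SPEC)


@pytest.fixture(scope="session")
def easy_preprocessor(easy_mc4_bundle):
    return Preprocessor(easy_mc4_bundle, 28, "dataset")


@pytest.fixture(scope="session")
def trained_tiny(easy_mc4_bundle, easy_preprocessor):
    """A tiny student trained to convergence on the easy 4-class problem
    (shared by the feature-separability and visualization tests)."""
    cfg = small_train_config(alpha=1.0, epochs=20, milestones=(12, 16), seed=11)
    student = build_student("tiny", easy_mc4_bundle.task, seed=11)
    student, history = train_student(student, easy_mc4_bundle, cfg,
                                     preprocess=easy_preprocessor)
    return student, history
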