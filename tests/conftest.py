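import numpy as np
import pytest

from organnot.seq_io import load_genetic_code
from organnot.intron_classifier import calibrate_splice_model, default_splice_models
from organnot.pipeline import default_bundle


@pytest.fixture(scope="session")
def code1():
    return load_genetic_code(1)


@pytest.fixture(scope="session")
def code4():
    return load_genetic_code(4)


@pytest.fixture(scope="session")
def splice_models():
    models = default_splice_models()
    for i, (g, m) in enumerate(sorted(models.items())):
        calibrate_splice_model(m, seed=100 + i)
    return models


@pytest.fixture(scope="session")
def bundle():
    """One fully calibrated model bundle shared across the whole session."""
    b = default_bundle()
    b.calibrate_all(seed=0, n_samples=200)
    return b


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
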