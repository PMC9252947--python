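import numpy as np
import pytest

from petnorm.bnn_model import ModelConfig, TrainConfig
from petnorm.phantom import PhantomConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_phantom_config():
    """Smallest usable cohort: 32x32 in-plane, shallow stacks."""
    return PhantomConfig(n_train=3, n_eval_normal=1, n_eval_abnormal=2,
                         shape=(32, 32, 4))


@pytest.fixture(scope="session")
def tiny_model_config():
    return ModelConfig(depth=2, base_channels=2, dropout_rate=0.0)


@pytest.fixture(scope="session")
def tiny_train_config():
    return TrainConfig(epochs=2, batch_size=8, seed=7)
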