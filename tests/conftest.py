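import numpy as np
import pytest

from spineseg import arch, phantom, train


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def tiny_model_config(**overrides) -> arch.ModelConfig:
    """A 16x16 configuration small enough for exhaustive checks."""
    base = dict(
        input_size=16,
        encoder_filters=(4, 6, 8),
        bottleneck_filters=12,
        decoder_filters=(8, 6, 4, 3),
        inception=arch.InceptionConfig(2, 3, 4, 2, 3, 2),
        plain_first_filters=4,
        dropout_rate=0.0,
    )
    base.update(overrides)
    return arch.ModelConfig(**base)


@pytest.fixture()
def tiny_config():
    return tiny_model_config()


@pytest.fixture(scope="session")
def phantom_pairs_32():
    """24 binary phantom pairs at 32x32 for fast training smoke tests."""
    return phantom.generate_dataset(
        phantom.PhantomConfig(size=32), n=24, seed=99, n_classes=2)


def small_train_config(**overrides) -> train.TrainConfig:
    """Training config matched to the 32x32 phantom fixture."""
    model = arch.ModelConfig(
        input_size=32,
        encoder_filters=(8, 16, 32),
        bottleneck_filters=64,
        decoder_filters=(32, 16, 8, 4),
        inception=arch.InceptionConfig().scaled(0.125),
        plain_first_filters=8,
    )
    base = dict(epochs=2, loss_name="dice", seed=7, batch_size=4,
                learning_rate=1e-3, model=model)
    base.update(overrides)
    return train.TrainConfig(**base)


@pytest.fixture(scope="session")
def trained_small(phantom_pairs_32):
    """A briefly trained 32x32 model shared by evaluation/Grad-CAM tests."""
    cfg = small_train_config(epochs=10)
    model, run, split = train.fit(cfg, phantom_pairs_32)
    return model, run, split, phantom_pairs_32
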