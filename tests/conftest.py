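import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ildim.config import (FusionConfig, ImageEncoderConfig, ModelConfig,
                          SequenceEncoderConfig, TextEncoderConfig)
from ildim.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_model_config():
    """Miniature architecture used for oracle and gradient tests."""
    return ModelConfig(
        d_model=8,
        image_size=16,
        series_length=5,
        image_encoder=ImageEncoderConfig(in_channels=1, channels=(2,), kernel_size=3),
        sequence_encoder=SequenceEncoderConfig(channels=2, hidden_size=3),
        text_encoder=TextEncoderConfig(vocab_size=30, heads=2),
        fusion=FusionConfig(heads=2),
    )


@pytest.fixture
def tiny_generator_config(tiny_model_config):
    mc = tiny_model_config
    return GeneratorConfig(
        n_cases=8,
        n_controls=6,
        image_size=mc.image_size,
        series_length=mc.series_length,
        series_channels=mc.sequence_encoder.channels,
        vocab_size=mc.text_encoder.vocab_size,
        rng_seed=7,
    )


@pytest.fixture
def tiny_dataset(tiny_generator_config):
    return generate_dataset(tiny_generator_config)


def finite_difference(f, arr, entries, step=1e-5):
    """Central finite-difference gradient of scalar f at selected flat
    entries of ``arr`` (mutated in place and restored)."""
    flat = arr.reshape(-1)
    grads = np.empty(len(entries))
    for k, i in enumerate(entries):
        orig = flat[i]
        flat[i] = orig + step
        up = f()
        flat[i] = orig - step
        down = f()
        flat[i] = orig
        grads[k] = (up - down) / (2 * step)
    return grads


def relative_error(a, b, floor=1e-6):
    return np.abs(a - b) / np.maximum(np.maximum(np.abs(a), np.abs(b)), floor)
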