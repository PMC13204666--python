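import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")

from ppgarr.dataset import LabeledDataset
from ppgarr.models import ModelConfig
from ppgarr.simulate import SimConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def smoke_config():
    """The reduced architecture used for fast shape/training checks:
    1-s (100-sample) inputs, widths 8/16/32, 16 hidden units, one 64-wide
    classifier layer."""
    return ModelConfig(input_length=100, block_widths=(8, 16, 32),
                       bilstm_hidden_per_direction=16, classifier_hidden=(64,),
                       dropout=0.5)


@pytest.fixture(scope="session")
def tiny_dataset() -> LabeledDataset:
    """60 default-noise synthetic segments, 10 per rhythm class."""
    return generate_dataset(SimConfig(seed=7, class_counts=(10,) * 6))


@pytest.fixture
def random_labels_dataset(rng) -> LabeledDataset:
    """Structureless segments with imbalanced labels, for split tests."""
    labels = np.repeat(np.arange(6), [40, 17, 9, 5, 12, 30])
    rng.shuffle(labels)
    return LabeledDataset(rng.standard_normal((len(labels), 50)), labels)
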