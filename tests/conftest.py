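import numpy as np
import pytest

from rna3wj.model import JunctionDataset, ModelConfig
from rna3wj.synthetic import SyntheticSpec, generate_records


@pytest.fixture(scope="session")
def tiny_records():
    """A handful of synthetic chains shared across model tests."""
    return generate_records(SyntheticSpec(count=8, seed=42))


@pytest.fixture(scope="session")
def tiny_dataset(tiny_records):
    return JunctionDataset.from_records(tiny_records)


@pytest.fixture()
def fast_config():
    """Small, quick training configuration for smoke-level fits."""
    return ModelConfig(hidden_dim=16, max_epochs=5, batch_size=4,
                       val_fraction=0.0, dropout=0.0)
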