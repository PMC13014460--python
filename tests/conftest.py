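import numpy as np
import pytest

from mvitoxnet.chem_io import DatasetSplit
from mvitoxnet.synthetic import SyntheticConfig, generate_dataset
from mvitoxnet.training import TrainingConfig, train

#: small model widths used throughout the suite to keep NumPy training fast
SMALL_MODEL = dict(embed_dim=16, conv_channels=16, repr_dim=16, fc_hidden=32)


@pytest.fixture(scope="session")
def small_records():
    """120 noise-free synthetic molecules, 30% toxicophore-positive."""
    return generate_dataset(SyntheticConfig(n=120, positive_fraction=0.3, seed=7))


@pytest.fixture(scope="session")
def tiny_store(small_records):
    """A 4-epoch checkpoint store trained on a tiny split (shared, read-only)."""
    split = DatasetSplit(train=small_records[:80], validation=small_records[80:100], seed=0)
    tc = TrainingConfig(learning_rate=1e-3, batch_size=32, epochs=4, kappa=0.2, seed=0)
    return train(split, tc, model_overrides=SMALL_MODEL)
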