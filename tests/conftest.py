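import numpy as np
import pytest

import transpred as tp
from transpred.features import encode_dataset


@pytest.fixture(scope="session")
def property_table():
    return tp.load_property_table()


@pytest.fixture(scope="session")
def residue_classes():
    return tp.load_residue_classes()


@pytest.fixture(scope="session")
def separable_dataset():
    """Well-separated 8-class synthetic dataset with AAC features."""
    config = tp.SimConfig(n_per_class=20, separation=0.25, seed=42, mean_length=120)
    sequences, manifest, _ = tp.make_dataset(config)
    X = encode_dataset(sequences, "AAC").to_numpy()
    labels = np.array([manifest.labels[s.id] for s in sequences])
    return sequences, manifest, X, labels


@pytest.fixture
def small_pssm():
    """A tiny hand-checkable profile: 1 position, query residue A, scores 1..20."""
    return tp.PssmProfile("probe", "A", np.arange(1, 21).reshape(1, 20))
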