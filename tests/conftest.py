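import numpy as np
import pytest

import multikano as mk


@pytest.fixture(scope="session")
def tiny_config():
    """Small, quickly separable study conditions for unit tests."""
    return mk.SimConfig(
        n_types=3, cells_per_type=15, n_genes=40, n_peaks=60,
        signature_fraction=0.15, effect_size=3.0, seed=7,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return mk.generate_paired_dataset(tiny_config)


@pytest.fixture(scope="session")
def fast_train_config():
    """Few-epoch training settings for smoke-level fits."""
    return mk.TrainConfig(epochs=40, hidden=(16,), seed=0)


@pytest.fixture(scope="session")
def tiny_features(tiny_dataset):
    """Preprocessed feature matrix + metadata for the tiny dataset."""
    pre = mk.Preprocessor(mk.PreprocessConfig(n_hvg=30)).fit(tiny_dataset)
    x = pre.transform(tiny_dataset)
    return x, tiny_dataset.labels, tiny_dataset.barcodes, pre
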