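"""Shared fixtures: synthetic recordings and epoch sets at test scale."""

import numpy as np
import pytest

from seizurecnn import benchmark, cnn, synthetic


@pytest.fixture(scope="session")
def balanced_epochs():
    """200 epochs/class, 6 channels, 256 Hz, per-segment random phases."""
    epochs, _ = benchmark.benchmark_epochs(seed=42)
    return epochs


@pytest.fixture(scope="session")
def balanced_spectra():
    _, spectra = benchmark.benchmark_epochs(seed=42)
    return spectra


@pytest.fixture(scope="session")
def experiment_cnn_config():
    def build(input_shape, n_classes, seed=42):
        return cnn.CNNConfig(
            input_shape=input_shape, n_classes=n_classes, seed=seed, **benchmark.BENCHMARK_CNN
        )

    return build


@pytest.fixture
def short_record():
    """28-s record with one 4-s seizure, used by io/segmentation tests."""
    cfg = synthetic.SyntheticConfig(
        timeline=[("interictal", 10.0), ("preictal", 4.0), ("ictal", 4.0), ("interictal", 10.0)],
        n_channels=2,
        seed=7,
    )
    return synthetic.generate_record(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
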