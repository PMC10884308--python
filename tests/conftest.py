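import numpy as np
import pytest

import skatesense as sk
from skatesense.network import Hyperparams


@pytest.fixture(scope="session")
def default_truth():
    return sk.SyntheticTruth(seed=11)


@pytest.fixture(scope="session")
def records(default_truth):
    return sk.generate_dataset(default_truth)


@pytest.fixture(scope="session")
def skater_dataset(records):
    datasets = sk.build_datasets(records)
    assert len(datasets) == 1
    return datasets[0]


@pytest.fixture(scope="session")
def fast_hp():
    """Short training budget for tests that only exercise plumbing."""
    return Hyperparams(max_epochs=300)


@pytest.fixture(scope="session")
def small_ensemble(skater_dataset, fast_hp):
    """A small trained+filtered ensemble shared across sweep/ensemble tests."""
    spec = sk.EnsembleSpec(n_iterations=30, b=10)
    return sk.build_ensemble(skater_dataset, m=5, spec=spec, master_seed=11,
                             hyperparams=fast_hp)


def stub_trained_model(e, E, seed=0):
    """TrainedModel carrying only selection statistics (no network)."""
    return sk.TrainedModel(network=None, e=float(e), E=float(E), seed=seed, split_id=seed)


class AffineStubNetwork:
    """Duck-typed network: scaled output = bias + coeffs . scaled inputs."""

    def __init__(self, bias=0.5, coeffs=(0.0, 0.0, 0.0)):
        self.bias = bias
        self.coeffs = np.asarray(coeffs, dtype=float)

    def predict_scaled(self, x):
        return self.bias + x @ self.coeffs


@pytest.fixture
def affine_stub():
    return AffineStubNetwork
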