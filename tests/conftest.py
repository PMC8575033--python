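import numpy as np
import pytest

from xomivae.model import XOmiHyperparams, train
from xomivae.synthetic import SyntheticSpec, generate_dataset

# Small planted-signal dataset used across module tests: 3 classes, 10
# planted genes each, sex-analogue covariate on gene 0.
TINY_SPEC = SyntheticSpec(
    n_samples=210, n_genes=300, n_classes=3, planted_genes_per_class=10,
    effect_size=0.4, noise_sd=0.1, sex_gene_index=0, seed=1)

TINY_HPARAMS = XOmiHyperparams(
    latent_dim=8, encoder_hidden=(64,), classifier_hidden=(32, 16),
    epochs_unsupervised=15, epochs_supervised=80, seed=2)


@pytest.fixture(scope="session")
def tiny_data():
    return generate_dataset(TINY_SPEC)


@pytest.fixture(scope="session")
def tiny_matrix(tiny_data):
    return tiny_data[0]


@pytest.fixture(scope="session")
def tiny_truth(tiny_data):
    return tiny_data[1]


@pytest.fixture(scope="session")
def tiny_model(tiny_matrix):
    return train(tiny_matrix, TINY_HPARAMS)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
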