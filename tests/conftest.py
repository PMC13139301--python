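import numpy as np
import pytest

from cpifusion.synthetic_fixtures import SignalSpec, generate_cpi_dataset

#: A compact nonstandard architecture for training-mechanics tests:
#: same topology as the default model, a fraction of the width.
SMALL_MODEL = dict(
    embedding_dim=16,
    compound_conv_filters=(8, 16),
    compound_kernel_sizes=(3, 5),
    protein_conv_filters=(8, 16),
    protein_kernel_sizes=(3, 7),
    compound_local_out=16,
    protein_local_out=16,
    compound_global_out=32,
    protein_global_out=32,
    fusion_hidden=(64,),
    nonstandard=True,
)


@pytest.fixture(scope="session")
def small_dataset():
    """120-pair planted-signal dataset, moderate noise."""
    dataset, meta = generate_cpi_dataset(30, 8, 0.5, seed=42)
    return dataset, meta


@pytest.fixture(scope="session")
def noiseless_dataset():
    """400-pair zero-noise dataset: the labels are an exact function of features."""
    dataset, meta = generate_cpi_dataset(80, 10, 0.5, spec=SignalSpec(sigma=0.0), seed=7)
    return dataset, meta


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
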