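import numpy as np
import pytest

from swisseg.swis_pipeline import load_benchmark
from swisseg.synthetic_scenes import DomainParams, SceneSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def tiny_dataset_dir(tmp_path_factory):
    """A small rendered two-domain dataset shared across tests."""
    out = tmp_path_factory.mktemp("tiny_ds")
    generate_dataset(SceneSpec(), DomainParams.lab(), DomainParams.field(1.0),
                     n_lab=20, n_field=10, seed=7, out_dir=out)
    return out


@pytest.fixture(scope="session")
def tiny_data(tiny_dataset_dir):
    return load_benchmark(tiny_dataset_dir)
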