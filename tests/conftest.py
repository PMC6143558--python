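import numpy as np
import pytest

from evoprofiler.synthetic import LineageConfig, generate_lineage_dataset
from evoprofiler.toy_model import generate_toy_model


@pytest.fixture(scope="session")
def toy_model():
    return generate_toy_model()


@pytest.fixture(scope="session")
def zero_noise_dataset():
    """Small lineage with zero noise: classification must equal truth."""
    cfg = LineageConfig(
        lineage_id="pgi",
        n_components={"metabolite": 30, "transcript": 40, "flux": 20},
        noise_sd=0.0,
        n_endpoints=2,
        n_replicates=3,
    )
    return generate_lineage_dataset(cfg, seed=1234)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
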