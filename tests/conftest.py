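import numpy as np
import pytest

from pfgmco.nets import EncoderConfig, build_modality_model
from pfgmco.synthetic import SyntheticSpec, generate_federation


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_model():
    """A small float64 modality model for gradient and API tests."""
    return build_modality_model(
        EncoderConfig("tiny_cnn_3d", d_feat=8, seed=5, input_shape=(8, 8, 8)))


@pytest.fixture(scope="session")
def small_federation():
    """Three clients x 24 subjects at 8^3/4^3 — cheap engine-level fixture."""
    spec = SyntheticSpec(n_clients=3, n_per_client=24, shape_s=(8, 8, 8),
                         lesion_center=(4, 4, 4), lesion_radius=2.0,
                         seed=11)
    return spec, generate_federation(spec)
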