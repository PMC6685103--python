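import numpy as np
import pytest

from dtfconn import GroundTruthNetwork, MVARModel, MultichannelRecording


@pytest.fixture
def bivariate_net():
    """The worked 2-channel example: unidirectional coupling 1 -> 2 of 0.5."""
    return GroundTruthNetwork(
        coupling=np.array([[[0.0, 0.0], [0.5, 0.0]]]), noise_sd=1.0
    )


@pytest.fixture
def bivariate_model(bivariate_net):
    """The same system as an exactly-known fitted model."""
    return MVARModel(
        order=1,
        coeffs=bivariate_net.coupling,
        noise_cov=np.eye(2),
        n_samples_used=0,
    )


@pytest.fixture
def white_noise_rec():
    rng = np.random.default_rng(42)
    return MultichannelRecording(
        data=rng.standard_normal((4, 4000)), fs=250.0
    )
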