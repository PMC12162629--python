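import numpy as np
import pytest

from dvamda import AssociationMatrix, SyntheticConfig, generate


@pytest.fixture(scope="session")
def toy_assoc() -> AssociationMatrix:
    """4 microbes x 3 diseases with a handful of links."""
    values = np.array(
        [
            [1, 0, 1],
            [0, 1, 0],
            [1, 1, 0],
            [0, 0, 1],
        ]
    )
    return AssociationMatrix(values)


@pytest.fixture(scope="session")
def small_truth():
    """A small planted matrix that trains in well under a second per fit."""
    return generate(SyntheticConfig(m=60, n=12, r=3, p_in=0.5, p_out=0.02, seed=1))


@pytest.fixture(scope="session")
def small_assoc(small_truth):
    return small_truth.association


# model parameters small enough for sub-second training in unit tests
FAST_MODEL = dict(hidden_dim=16, latent_dim=16, predictor_hidden=16, epochs=60)


@pytest.fixture(scope="session")
def fast_params():
    return dict(FAST_MODEL)
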