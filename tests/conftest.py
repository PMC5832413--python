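import numpy as np
import pytest

from rsapipe import synth
from rsapipe.rdm import RDM


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def model_rdms():
    """Near-orthogonal 12-object model RDM pair used across tests."""
    return synth.make_model_rdms(12, seed=1)


@pytest.fixture(scope="session")
def small_config():
    return synth.SyntheticConfig(
        n_objects=12, n_subjects=6, n_runs=3, grid=(10, 10, 10),
        regions={
            "loc_like": synth.RegionSpec(
                (slice(1, 4), slice(1, 4), slice(1, 4)),
                {"visual": (0.8, 0.0), "conceptual": (0.0, 0.0)}, False),
            "prc_like": synth.RegionSpec(
                (slice(6, 9), slice(6, 9), slice(6, 9)),
                {"visual": (0.45, 0.45), "conceptual": (0.45, 0.45)}, True),
        },
        noise_sd=0.6, seed=7,
    )


@pytest.fixture
def toy_rdm():
    vals = np.array([
        [0.0, 0.2, 0.9, 0.7],
        [0.2, 0.0, 0.6, 0.8],
        [0.9, 0.6, 0.0, 0.3],
        [0.7, 0.8, 0.3, 0.0],
    ])
    return RDM(vals, ["a", "b", "c", "d"], measure="one_minus_normalized_rating")


def tau_a_oracle(x, y):
    """Exhaustive O(m^2) pair enumeration, independent of the package path."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    m = len(x)
    cd = 0
    for i in range(m):
        for j in range(i):
            cd += np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
    return cd / (m * (m - 1) / 2)
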