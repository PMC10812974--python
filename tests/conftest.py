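import numpy as np
import pytest

from myoflex.materials import MuscleParams


@pytest.fixture(scope="session")
def params():
    return MuscleParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_muscle_states(rng, n, j_range=(0.95, 1.05), spread=0.08):
    """Random deformation gradients with controlled J and unit fiber axes."""
    out = []
    while len(out) < n:
        F = np.eye(3) + spread * rng.standard_normal((3, 3))
        J = np.linalg.det(F)
        if J <= 0.1:
            continue
        F *= (rng.uniform(*j_range) / J) ** (1.0 / 3.0)
        N = rng.standard_normal(3)
        N /= np.linalg.norm(N)
        out.append((F, N))
    return out
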