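import numpy as np
import pytest

from procdl import Dictionary, LearnConfig, learn
from procdl.synthetic_benchmark import generate_instance


@pytest.fixture(scope="session", autouse=True)
def _warm_jit():
    """Trigger one-time kernel compilation so per-test timings are honest."""
    inst = generate_instance(8, 12, 40, 2, 20.0, 0)
    for algo in ("rsvd", "ksvd"):
        learn(inst.Y, LearnConfig(m=12, k=2, s=3, T=1, seed=0, algorithm=algo))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dictionary(rng, n, m):
    D = rng.standard_normal((n, m))
    return Dictionary(D=D / np.linalg.norm(D, axis=0))


@pytest.fixture
def small_instance():
    """A mid-noise synthetic instance small enough for exhaustive checks."""
    return generate_instance(10, 20, 60, 3, 20.0, 7)
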