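import numpy as np
import pytest

from cyclepop import PDEParams


@pytest.fixture
def realistic_params():
    """22-hour cycle: 8 h G1, 14 h G2 (v=1/16, u=1/28)."""
    return PDEParams.from_ratio(1 / 16, 1 / 28, 10**-0.605)


def random_parameter_sets(n, seed, s_log_range=(-3.0, 3.0)):
    """(v, u, s) triples with phase lengths 1-25 h and a wide initial ratio."""
    rng = np.random.default_rng(seed)
    v = rng.uniform(0.02, 0.5, n)
    u = rng.uniform(0.02, 0.5, n)
    s = 10.0 ** rng.uniform(*s_log_range, n)
    return list(zip(v, u, s))


@pytest.fixture
def param_sweep():
    return random_parameter_sets(30, seed=42)
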