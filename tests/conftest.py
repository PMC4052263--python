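import numpy as np
import pytest

from cernet import KineticParams


@pytest.fixture
def default_params() -> KineticParams:
    return KineticParams()


@pytest.fixture
def golden_pair_params() -> KineticParams:
    """Symmetric pair whose fixed point is the golden-ratio conjugate."""
    return KineticParams(g_R=1, g_T=1, d_R=1, d_T=1, d_C=1, u_C=0, b=1, alpha=1)


def random_params(rng: np.random.Generator) -> KineticParams:
    """A random valid parameter set within the biologically plausible range."""
    return KineticParams(
        g_R=rng.uniform(0.5, 2.0),
        g_T=rng.uniform(0.5, 2.0),
        b=rng.uniform(0.1, 1.0),
        u_C=rng.uniform(0.0, 0.2),
        d_R=rng.uniform(0.05, 0.5),
        d_T=rng.uniform(0.05, 0.5),
        d_C=rng.uniform(0.05, 0.5),
        alpha=rng.uniform(0.1, 1.0),
    )
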