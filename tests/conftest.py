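import numpy as np
import pytest

import ecospectra as es


@pytest.fixture(scope="session")
def small_lv_community():
    """A modest stable mixed community reused across oracle tests."""
    params = es.LVParams(N=60, c=10, sigma2=0.02, gamma=0.3, b=1.5, seed=3)
    return es.sample_lv_community(params)


@pytest.fixture(scope="session")
def fig_trophic_params():
    """Bipartite community at the two-trophic-level demonstration setting."""
    return es.TrophicParams(Nx=100, Ny=200, cx=20, cy=10, alpha=5, b=1.0, d=1.0, seed=0)


@pytest.fixture(scope="session")
def fig_trophic_community(fig_trophic_params):
    return es.sample_trophic_community(fig_trophic_params)


def rel_l2(a, b):
    return float(np.linalg.norm(np.asarray(a) - np.asarray(b)) / np.linalg.norm(b))
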