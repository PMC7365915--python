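import numpy as np
import pytest

from statewalk.fixtures import MEF_LIKE_MODEL, ONE_STATE_MODEL
from statewalk.model import MixtureModel, StateParams
from statewalk.pdf import PdfEvalConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def mef_model() -> MixtureModel:
    """Two-state fibroblast-like mixture (session-shared, immutable)."""
    return MEF_LIKE_MODEL


@pytest.fixture(scope="session")
def one_state_model() -> MixtureModel:
    return ONE_STATE_MODEL


@pytest.fixture(scope="session")
def persistent_state() -> StateParams:
    """A single well-separated persistent state used across density tests."""
    return StateParams(mu_r=3.0, sigma_r=1.0, sigma_theta=0.7)


@pytest.fixture(scope="session")
def pcfg() -> PdfEvalConfig:
    return PdfEvalConfig()


@pytest.fixture(scope="session")
def pcfg_fast() -> PdfEvalConfig:
    """Coarser quadrature for tests that evaluate densities in bulk."""
    return PdfEvalConfig(n_quad=200)
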