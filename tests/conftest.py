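import numpy as np
import pytest

from xylreg.config import default_params
from xylreg.model import RegulonParameters


@pytest.fixture(scope="session")
def params():
    """The shipped default parameter set."""
    return default_params()


@pytest.fixture(scope="session")
def weak_params(params):
    """Weak-binding (monostable) control parameterization."""
    return params.replace(kf83=0.01)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def binding_only(params: RegulonParameters) -> RegulonParameters:
    """Zero out production and dilution, leaving only the binding reactions."""
    return params.replace(
        alpha3=0.0, beta3=0.0, alphaG1=0.0, betaG1=0.0, alpha80=0.0, beta80=0.0,
        alpha4=0.0, gamma=0.0, betaGFP=0.0, constitutive_rate=0.0,
    )


def birth_death_only(params: RegulonParameters) -> RegulonParameters:
    """Constant production and dilution only: no binding, no Hill activation."""
    return params.replace(
        beta3=0.0, betaG1=0.0, beta80=0.0, kf83=0.0, kr83=0.0, kf84=0.0, kr84=0.0,
        alphaG1=0.0, betaGFP=0.0,
    )
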