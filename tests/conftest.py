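import pytest

from ntdm import ModelParameters, build_system
from ntdm.engine import FracODESystem


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def smoking_system(params):
    return build_system(params)


@pytest.fixture(scope="session")
def scalar_total_system():
    """Scalar model of the compartment total: D^mu N = alpha - vartheta*N, N(0)=85."""
    return FracODESystem(
        names=("N",), constants=(1.0,), linear=((-0.05,),), bilinear=(), initial=(85.0,)
    )


@pytest.fixture(scope="session")
def linear_decay_system():
    """Scalar linear test problem D^mu x = -x, x(0)=1 with Mittag-Leffler solution."""
    return FracODESystem(
        names=("x",), constants=(0.0,), linear=((-1.0,),), bilinear=(), initial=(1.0,)
    )
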