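import numpy as np
import pytest

from morphocontract import ModelParameters
from morphocontract.fem import build_mesh


@pytest.fixture(scope="session")
def table2() -> ModelParameters:
    """The published default parameter set."""
    return ModelParameters.defaults()


@pytest.fixture(scope="session")
def consistent(table2) -> ModelParameters:
    """Defaults with the equilibrium identities enforced to machine precision."""
    return table2.consistent()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230324)


@pytest.fixture(scope="session")
def unit_mesh_coarse():
    return build_mesh(1.0, 0.25)


@pytest.fixture(scope="session")
def unit_mesh():
    return build_mesh(1.0, 0.1)
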