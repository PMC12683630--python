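import numpy as np
import pytest

from mbpip.conformers import minimize
from mbpip.io_units import Structure
from mbpip.mb_potential import MBPIPModel, default_interaction_specs
from mbpip.synthetic import ToyPotential, build_chain


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def butane():
    return build_chain(4, "linear")


@pytest.fixture(scope="session")
def octane_hairpin():
    return build_chain(8, "hairpin")


@pytest.fixture(scope="session")
def toy_low():
    return ToyPotential("low")


@pytest.fixture(scope="session")
def toy_high():
    return ToyPotential("high")


@pytest.fixture(scope="session")
def toy_high_minima_c8(toy_high):
    lin = minimize(toy_high, build_chain(8, "linear"), gtol=1e-7)
    hp = minimize(toy_high, build_chain(8, "hairpin"), gtol=1e-7)
    assert lin.converged and hp.converged
    return lin, hp


@pytest.fixture(scope="session")
def random_small_model():
    """A small all-order model with random coefficients on a C3H8-sized alphabet."""
    rng = np.random.default_rng(7)
    specs = default_interaction_specs(orders={2: 4, 3: 3, 4: 2},
                                      cutoffs={3: np.inf, 4: np.inf})
    coeffs = [rng.normal(0.0, 0.1, s.basis().n_functions) for s in specs]
    return MBPIPModel(specs, coeffs)


@pytest.fixture()
def random_structure(rng):
    """A well-spread 8-atom C3H5 configuration (no tiny distances)."""
    while True:
        coords = rng.normal(0.0, 3.0, (8, 3))
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        if d[np.triu_indices(8, 1)].min() > 1.5:
            return Structure(("C", "C", "C", "H", "H", "H", "H", "H"), coords)
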