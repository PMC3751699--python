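import numpy as np
import pytest

from ppi_kinetics import (ChiSquareReference, KineticParameters,
                          load_fitted_kinetics, load_interactome_summaries,
                          load_reference_observables)

# observables fitted to the reference yeast interactome, with percent SEs
REFERENCE_OBSERVABLES = {
    "A1": (3184.82, 32), "A2": (49.8628, 77), "beta1": (4.80485, 29),
    "beta2": (2.1242, 20), "xi_r": (6.30779, 51),
    "p1": (0.73526, 13), "p2": (0.000552383, 5),
}
YEAST_N = 4135


@pytest.fixture(scope="session")
def kp_best() -> KineticParameters:
    """Best-estimate kinetic rates shipped with the package."""
    return load_fitted_kinetics()


@pytest.fixture(scope="session")
def reference() -> ChiSquareReference:
    return load_reference_observables()


@pytest.fixture(scope="session")
def summaries():
    return load_interactome_summaries()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
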