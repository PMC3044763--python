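import numpy as np
import pytest

from myoarch.domains import ShapeSpec, make_domain
from myoarch.kinetics import IntegrinState, ModelParams


@pytest.fixture(scope="session")
def small_stair():
    """Stair island small enough for brute-force pair oracles."""
    return make_domain(ShapeSpec("stair", stair_steps=1), resolution=8)


@pytest.fixture(scope="session")
def small_square():
    return make_domain(ShapeSpec("square"), resolution=10)


@pytest.fixture()
def params():
    return ModelParams()


def uniform_state(domain, params, rho_p=0.0, rho_n=0.0):
    n = domain.n_points
    rho_p = np.full(n, float(rho_p))
    rho_n = np.full(n, float(rho_n))
    total = params.phi0 * domain.area
    free = total - domain.delta_area * (rho_p + rho_n).sum()
    rho_f = np.full(n, free / domain.area)
    return IntegrinState(rho_f, rho_p, rho_n)
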