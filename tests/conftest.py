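import numpy as np
import pytest

from softmpm import MaterialParams, SimConfig, SpecimenSpec


@pytest.fixture
def params():
    """Default material: E = 10 kPa at zero Poisson ratio, moderate hardening."""
    return MaterialParams()


@pytest.fixture
def small_cfg():
    """Desk-scale grid for fast unit-level simulations."""
    return SimConfig(domain_extent=(96, 32))


@pytest.fixture
def small_spec():
    """A small slab (~400 particles) spanning 20 x 5 cells."""
    return SpecimenSpec(extents=(0.05, 0.0125), particles_per_cell=4)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_elastic_F(rng, n, params, d=2, spread=0.04):
    """Random deformation gradients whose volume ratio stays in the elastic
    band [1 - theta_c, 1 + theta_s] (rejection sampling)."""
    out = []
    while len(out) < n:
        F = np.eye(d) + spread * rng.standard_normal((d, d))
        J = np.linalg.det(F)
        if 1.0 - params.theta_c < J < 1.0 + params.theta_s:
            out.append(F)
    return np.array(out)
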