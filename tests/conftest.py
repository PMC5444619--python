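import numpy as np
import pytest

from atherosim.lattice import GeometrySpec, build_artery


@pytest.fixture()
def small_spec():
    """A small artery that still has every structural feature."""
    return GeometrySpec(lumen_radius_um=600.0, wall_thickness_um=300.0,
                        length_um=1500.0)


@pytest.fixture()
def small_artery(small_spec):
    return build_artery(small_spec)


@pytest.fixture()
def rng():
    return np.random.Generator(np.random.PCG64(12345))


# -- session-scoped heavy fixtures shared by the acceptance tests -------------

@pytest.fixture(scope="session")
def anchor_fixture():
    """The 1.0 mm spherical-plaque artery at full (published) geometry."""
    from atherosim.experiments import build_plaque_fixture

    lat, pop = build_plaque_fixture(1000.0)
    return lat, pop


@pytest.fixture(scope="session")
def anchor_cycle_fields(anchor_fixture):
    """Per-phase EC wall shear stress over one cardiac cycle (80 solves)."""
    from atherosim.experiments import cycle_wss_fields

    lat, _ = anchor_fixture
    return cycle_wss_fields(lat)


@pytest.fixture(scope="session")
def calibrated_kappa(anchor_cycle_fields):
    from atherosim.experiments import calibrate_kappa

    return calibrate_kappa(anchor_cycle_fields)
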