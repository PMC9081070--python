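import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from cztcam import (
    CrystalSpec, AnodeArraySpec, FieldConfig, CarrierParams, build_grid,
    solve_electric_potential, solve_weighting_potential,
)

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def crystal():
    return CrystalSpec()


@pytest.fixture(scope="session")
def anodes():
    return AnodeArraySpec()


@pytest.fixture(scope="session")
def small_grid(crystal, anodes):
    """3x3 anode neighbourhood at a desk-scale step (0.41 mm)."""
    return build_grid(crystal, anodes, neighbourhood=3, step=0.41)


@pytest.fixture(scope="session")
def plate_grid():
    """Parallel-plate degenerate geometry: one full-area anode."""
    c = CrystalSpec(width_x=6.0, width_y=6.0, thickness=5.0)
    a = AnodeArraySpec(n_x=1, n_y=1, pitch=0.5, pad_size=0.5)
    return c, a, build_grid(c, a, neighbourhood=1, step=0.125)


@pytest.fixture(scope="session")
def plate_fields(plate_grid):
    """Uniform field and linear weighting potential on the plate grid."""
    c, a, grid = plate_grid
    cfg = FieldConfig(electric_alternative="A1", weighting_alternative="B1")
    phi = solve_electric_potential(grid, c, cfg)
    phi_k = solve_weighting_potential(grid, 0, cfg)
    return phi, phi_k


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
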