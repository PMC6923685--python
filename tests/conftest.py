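import numpy as np
import pytest

from tmaskit import CartesianGrid, Medium, TransducerSpec, rayleigh_field

FREQ = 1e6
FOCUS = 0.023
APERTURE = 0.0235


@pytest.fixture(scope="session")
def medium():
    return Medium(density=1000.0, sound_speed=1450.0, conductivity=1.0)


@pytest.fixture(scope="session")
def spec():
    return TransducerSpec(
        carrier_frequency=FREQ,
        geometric_focus=FOCUS,
        aperture_diameter=APERTURE,
        surface_drive=1.0,
    )


@pytest.fixture(scope="session")
def small_grid(medium):
    """Quarter-wavelength grid around the focus, symmetric about the axis."""
    lam = medium.wavelength(FREQ)
    return CartesianGrid.centered(0.006, (0.015, 0.031), 0.006, lam / 4)


@pytest.fixture(scope="session")
def small_field(spec, medium, small_grid):
    """Rayleigh-integral field on the small focal-region grid (computed once)."""
    return rayleigh_field(spec, medium, small_grid)


def axis_indices(grid):
    """(ix, iz) of the beam axis on a grid whose x/z axes contain 0."""
    ix = int(np.argmin(np.abs(grid.x)))
    iz = int(np.argmin(np.abs(grid.z)))
    assert grid.x[ix] == 0.0 and grid.z[iz] == 0.0
    return ix, iz
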