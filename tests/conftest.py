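import numpy as np
import pytest

import sefmd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def harmonic_1dof():
    """1-DOF quadratic surface with a mid-infrared frequency (0.01 au)."""
    return sefmd.build_harmonic_surface([[1.0e-4]], [0.0])


@pytest.fixture
def coupled_pair():
    """Deterministic 2-DOF coupled quadratic fixture (seed 1)."""
    _, surface = sefmd.make_fixture("coupled_pair_2d", seed=1)
    return surface


@pytest.fixture
def morse_unit():
    """Unit Morse oscillator (depth 1, width 1) for order tests."""
    return sefmd.build_morse_surface(1.0, 1.0)


@pytest.fixture
def water_like_system(rng):
    """Synthetic nonlinear triatomic with a positive-definite quadratic
    Cartesian surface (not a fit to any real molecule)."""
    from sefmd.molecular_frame import AMU_TO_ME

    geometry = np.array([0.0, 0.0, 0.0, 1.8, 0.0, 0.0, -0.45, 1.75, 0.0])
    masses = np.array([16.0, 1.0, 1.0]) * AMU_TO_ME
    system = sefmd.MolecularSystem(["O", "H", "H"], masses, geometry)
    a = rng.normal(size=(9, 9)) * 1.0e-2
    surface = sefmd.build_harmonic_surface(a @ a.T, geometry)
    return system, surface


def zpe_site_state(surface):
    basis = sefmd.dof_normal_modes(surface)
    return basis, sefmd.site_zpe_state(basis, surface.reference_geometry)


def harmonic_diatomic(k=0.1, m=1000.0, r=2.0):
    """Two equal masses on a spring along x: single vibration sqrt(2k/m)."""
    geometry = np.array([0.0, 0.0, 0.0, r, 0.0, 0.0])
    system = sefmd.MolecularSystem(["X", "X"], [m, m], geometry)
    h = np.zeros((6, 6))
    h[0, 0] = h[3, 3] = k
    h[0, 3] = h[3, 0] = -k
    surface = sefmd.build_harmonic_surface(h, geometry)
    return system, surface
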