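import numpy as np
import pytest

import ovomag as om


@pytest.fixture(scope="session")
def default_load() -> om.EggLoad:
    """Particle load of the default study conditions (25% zona coverage)."""
    n = om.particles_from_coverage(0.25)
    return om.EggLoad(n_particles=n, particle=om.ESTAPOR_PARTICLE)


@pytest.fixture(scope="session")
def magnet_small() -> om.MagnetSpec:
    return om.MAGNETS["S-02-02"]


def biot_savart_axial(magnet: om.MagnetSpec, z, n_loops: int = 2000):
    """Independent numerical oracle: the magnet as a stack of surface-current
    loops, each contributing the Biot-Savart on-axis loop field."""
    R, L, Br = magnet.radius, magnet.length, magnet.remanence
    zi = (np.arange(n_loops) + 0.5) * L / n_loops
    dz = L / n_loops
    z = np.atleast_1d(np.asarray(z, dtype=float))
    out = np.empty_like(z)
    for k, zz in enumerate(z):
        out[k] = 0.5 * Br * np.sum(R**2 * dz / (R**2 + (zz + zi) ** 2) ** 1.5)
    return out
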