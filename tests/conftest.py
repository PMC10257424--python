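import numpy as np
import pytest

import mpmri as m

VIABLE_PARAMS = {
    "t1_ms": 1500.0,
    "t2_ms": 60.0,
    "mt_attenuation": 0.30,
    "adc": 800.0,
    "r2star_s": 30.0,
    "g_d_kpa": 5.0,
    "g_l_kpa": 2.0,
    "proton_density": 1.0,
    "ha_density": 0.30,
}


def build_phantom(grid=None, heterogeneity=0.0, seed=0, core=False, **overrides):
    """Standard viable-tumour phantom used across the suite."""
    params = {**VIABLE_PARAMS, **overrides}
    necrotic = (
        {"t2_ms": 120.0, "adc": 2000.0, "proton_density": 0.9, "ha_density": 0.0}
        if core
        else None
    )
    rec = m.tumour_recipe(
        params=params,
        necrotic_core=necrotic,
        heterogeneity=heterogeneity,
        grid=grid or m.Grid(32, 32, 30.0),
        seed=seed,
    )
    return m.make_phantom(rec)


@pytest.fixture
def small_phantom():
    return build_phantom()


@pytest.fixture
def hetero_phantom():
    return build_phantom(heterogeneity=0.12, seed=7)


def homogeneous_modulus_phantom(gd_kpa=5.0, gl_kpa=2.0, grid=None):
    """Phantom whose G* field is constant everywhere (tumour and background)."""
    ph = build_phantom(grid=grid, g_d_kpa=gd_kpa, g_l_kpa=gl_kpa)
    g = np.full_like(ph.g_complex_pa, (gd_kpa + 1j * gl_kpa) * 1e3)
    return ph.with_fields(g_complex_pa=g)
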