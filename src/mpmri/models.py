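"""Closed-form signal models shared by the simulators and the map fitters.

The same equations are used on both sides of every simulate -> fit round
trip, so parameter recovery is a well-posed self-consistency contract.

IR-TrueFISP
-----------
After adiabatic inversion and an alpha/2 preparation, the balanced SSFP
signal relaxes mono-exponentially toward its steady state with an apparent
time constant T1* that mixes T1 and T2::

    S(t)    = S_ss * (1 - INV * exp(-t / T1*))
    1/T1*   = cos^2(a/2)/T1 + sin^2(a/2)/T2
    S_ss    = M0 * sin(a) / ((T1/T2 + 1) - cos(a) * (T1/T2 - 1))
    INV     = 1 + (M0 / S_ss) * sin(a/2)

with flip angle ``a`` and equilibrium magnetisation ``M0``.  The map
(T1, T2, M0) -> (S_ss, INV, T1*) is inverted in closed form: with
C = sin(a) * (INV - 1) / sin(a/2),

    T1/T2 = (C - 1 - cos(a)) / (1 - cos(a))
    T1    = T1* * (cos^2(a/2) + (T1/T2) * sin^2(a/2))

Diffusion and gradient-echo decays are mono-exponential in b and TE; the
shear wavefield is a time-harmonic plane wave with complex wavenumber
``k = omega * sqrt(rho / G*)`` (principal branch, so a lossy modulus gives a
spatially decaying ``exp(-i k x)`` factor under the ``exp(+i omega t)`` time
convention used throughout).
"""

from __future__ import annotations

import numpy as np

#: soft-tissue density assumed by the elastography model (kg/m^3)
TISSUE_DENSITY_KG_M3 = 1000.0


# --------------------------------------------------------------------------
# IR-TrueFISP three-parameter apparent-relaxation model


def ir_truefisp_params(t1_ms, t2_ms, m0, flip_deg):
    """Map tissue (T1, T2, M0) to the apparent parameters (S_ss, INV, T1*)."""
    t1 = np.asarray(t1_ms, dtype=float)
    t2 = np.asarray(t2_ms, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    if np.any(t1 <= 0) or np.any(t2 <= 0):
        raise ValueError("T1 and T2 must be positive")
    a = np.deg2rad(flip_deg)
    r = t1 / t2
    s_ss = m0 * np.sin(a) / ((r + 1.0) - np.cos(a) * (r - 1.0))
    t1_star = 1.0 / (np.cos(a / 2) ** 2 / t1 + np.sin(a / 2) ** 2 / t2)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 + np.where(s_ss > 0, m0 / np.where(s_ss > 0, s_ss, 1.0), np.nan) * np.sin(a / 2)
    return s_ss, inv, t1_star


def ir_truefisp_signal(t_ms, t1_ms, t2_ms, m0, flip_deg):
    """Signed IR-TrueFISP signal S(t); broadcastable over voxels and times."""
    s_ss, inv, t1_star = ir_truefisp_params(t1_ms, t2_ms, m0, flip_deg)
    t = np.asarray(t_ms, dtype=float)
    return s_ss * (1.0 - inv * np.exp(-t / t1_star))


def invert_ir_truefisp(s_ss, inv, t1_star_ms, flip_deg):
    """Recover (T1, T2) from fitted apparent parameters.

    Returns NaN where the apparent parameters are unphysical (INV <= 1 or a
    non-positive implied T1/T2 ratio); callers mask those voxels.
    """
    s_ss = np.asarray(s_ss, dtype=float)
    inv = np.asarray(inv, dtype=float)
    t1_star = np.asarray(t1_star_ms, dtype=float)
    a = np.deg2rad(flip_deg)
    c = np.sin(a) * (inv - 1.0) / np.sin(a / 2)
    r = (c - 1.0 - np.cos(a)) / (1.0 - np.cos(a))
    bad = ~np.isfinite(r) | (r <= 0) | (inv <= 1.0) | (t1_star <= 0)
    r = np.where(bad, np.nan, r)
    t1 = t1_star * (np.cos(a / 2) ** 2 + r * np.sin(a / 2) ** 2)
    t2 = t1 / r
    return t1, t2


# --------------------------------------------------------------------------
# mono-exponential decays


def dwi_signal(b_s_mm2, s0, adc_um2_s):
    """DWI decay S0*exp(-b*ADC); ADC given in 1e-6 mm^2/s."""
    b = np.asarray(b_s_mm2, dtype=float)
    return np.asarray(s0, dtype=float) * np.exp(-b * np.asarray(adc_um2_s, dtype=float) * 1e-6)


def mge_signal(te_ms, s0, r2star_s):
    """Gradient-echo decay S0*exp(-R2* * TE) with TE in ms, R2* in 1/s."""
    te_s = np.asarray(te_ms, dtype=float) * 1e-3
    return np.asarray(s0, dtype=float) * np.exp(-np.asarray(r2star_s, dtype=float) * te_s)


# --------------------------------------------------------------------------
# shear wave dispersion


def shear_wavenumber(g_complex_pa, frequency_hz, density_kg_m3=TISSUE_DENSITY_KG_M3):
    """Complex shear wavenumber k = omega * sqrt(rho / G*) (rad/m).

    Principal square root: for G* = G_d + i*G_l with G_l >= 0 the imaginary
    part of k is <= 0, so the plane-wave factor exp(-i k x) decays along the
    propagation direction with attenuation coefficient ``-Im(k)``.
    """
    g = np.asarray(g_complex_pa, dtype=complex)
    if np.any(g.real <= 0):
        raise ValueError("storage modulus must be positive")
    omega = 2.0 * np.pi * float(frequency_hz)
    return omega * np.sqrt(density_kg_m3 / g)


def shear_wavelength_m(g_complex_pa, frequency_hz, density_kg_m3=TISSUE_DENSITY_KG_M3):
    k = shear_wavenumber(g_complex_pa, frequency_hz, density_kg_m3)
    return 2.0 * np.pi / np.abs(k.real)


# --------------------------------------------------------------------------
# noise


def add_rician(signal, sigma, rng):
    """Rician-corrupt a (signed) signal: magnitude of signal + complex noise.

    Matches the physics of magnitude MR images: independent Gaussian noise of
    scale ``sigma`` on the real and imaginary channels, then magnitude.
    """
    s = np.asarray(signal, dtype=float)
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return np.abs(s)
    re = s + rng.normal(0.0, sigma, size=s.shape)
    im = rng.normal(0.0, sigma, size=s.shape)
    return np.hypot(re, im)
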