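"""Forward simulation of the five acquisitions over a digital phantom.

Magnitude sequences (IR-TrueFISP, MT-RARE, DWI, MGE) produce multi-frame
magnitude stacks with optional Rician noise; elastography produces real-valued
displacement snapshots of a time-harmonic shear wave with optional Gaussian
noise.  Noiseless frames follow the closed-form models in :mod:`mpmri.models`
exactly, which is the contract the fitters are tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import models
from .grid import Grid, MRE_GRID
from .phantom import Phantom
from .protocols import AcquisitionProtocol


@dataclass(frozen=True)
class SignalStack:
    """Multi-frame acquired signal plus the protocol that produced it.

    ``frames`` has shape (n_frames, ny, nx) for single-slice magnitude data
    and (n_frames, n_slices, ny, nx) for MRE displacement snapshots.
    ``frame_values`` are the semantic labels along the frame axis (inversion
    times, b-values, echo times, MT states or wave phases).
    """

    frames: np.ndarray
    frame_axis: str
    frame_values: tuple
    protocol: AcquisitionProtocol
    grid: Grid
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frames.shape[0] != len(self.frame_values):
            raise ValueError("frame count does not match frame labels")
        if self.frames.shape[0] != self.protocol.n_frames:
            raise ValueError("frame count does not match protocol")
        if self.protocol.modality != "MRE" and np.any(self.frames < 0):
            raise ValueError("magnitude frames must be non-negative")


def _noise_scale(protocol: AcquisitionProtocol, clean_frames: np.ndarray, viable: np.ndarray) -> float:
    """Absolute noise sd: protocol.noise_sigma relative to mean viable signal."""
    if protocol.noise_sigma == 0:
        return 0.0
    ref = np.abs(clean_frames[:, viable]).mean() if viable.any() else np.abs(clean_frames).mean()
    return float(protocol.noise_sigma * ref)


def _rng(protocol: AcquisitionProtocol) -> np.random.Generator:
    return np.random.default_rng(protocol.seed)


def simulate_ir_truefisp(phantom: Phantom, protocol: AcquisitionProtocol) -> SignalStack:
    """Inversion-recovery TrueFISP magnitude frames at the protocol's TIs."""
    if protocol.modality != "IR_TRUEFISP":
        raise ValueError("protocol modality must be IR_TRUEFISP")
    ti = np.asarray(protocol.inversion_times_ms, dtype=float)
    signed = models.ir_truefisp_signal(
        ti[:, None, None],
        phantom.t1_ms[None],
        phantom.t2_ms[None],
        phantom.proton_density[None],
        protocol.flip_deg,
    )
    sigma = _noise_scale(protocol, signed, phantom.viable_mask)
    frames = models.add_rician(signed, sigma, _rng(protocol))
    return SignalStack(
        frames=frames,
        frame_axis="inversion_time_ms",
        frame_values=tuple(ti),
        protocol=protocol,
        grid=phantom.grid,
        provenance={"noise_sigma_abs": sigma},
    )


def simulate_mt_pair(phantom: Phantom, protocol: AcquisitionProtocol) -> SignalStack:
    """Off/on resonance magnetisation-transfer pair.

    The off-resonance frame is proportional to proton density; the
    on-resonance frame is attenuated by the phantom's fractional saturation.
    """
    if protocol.modality != "MT_RARE":
        raise ValueError("protocol modality must be MT_RARE")
    if np.any((phantom.mt_attenuation < 0) | (phantom.mt_attenuation > 1)):
        raise ValueError("mt_attenuation must lie in [0, 1]")
    s_off = phantom.proton_density.astype(float)
    s_on = s_off * (1.0 - phantom.mt_attenuation)
    clean = np.stack([s_off, s_on])
    sigma = _noise_scale(protocol, clean, phantom.viable_mask)
    frames = models.add_rician(clean, sigma, _rng(protocol))
    return SignalStack(
        frames=frames,
        frame_axis="mt_state",
        frame_values=("off", "on"),
        protocol=protocol,
        grid=phantom.grid,
        provenance={"noise_sigma_abs": sigma},
    )


def simulate_dwi(phantom: Phantom, protocol: AcquisitionProtocol) -> SignalStack:
    """Diffusion-weighted frames S0 * exp(-b * ADC) at the protocol b-values."""
    if protocol.modality != "DWI":
        raise ValueError("protocol modality must be DWI")
    b = np.asarray(protocol.b_values, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    clean = models.dwi_signal(
        b[:, None, None], phantom.proton_density[None], phantom.adc[None]
    )
    sigma = _noise_scale(protocol, clean, phantom.viable_mask)
    frames = models.add_rician(clean, sigma, _rng(protocol))
    return SignalStack(
        frames=frames,
        frame_axis="b_value_s_mm2",
        frame_values=tuple(b),
        protocol=protocol,
        grid=phantom.grid,
        provenance={"noise_sigma_abs": sigma},
    )


def simulate_mge(phantom: Phantom, protocol: AcquisitionProtocol) -> SignalStack:
    """Multi-gradient-echo frames S0 * exp(-R2* * TE) along the echo train."""
    if protocol.modality != "MGE":
        raise ValueError("protocol modality must be MGE")
    te = np.asarray(protocol.echo_times_ms, dtype=float)
    clean = models.mge_signal(
        te[:, None, None], phantom.proton_density[None], phantom.r2star_s[None]
    )
    sigma = _noise_scale(protocol, clean, phantom.viable_mask)
    frames = models.add_rician(clean, sigma, _rng(protocol))
    return SignalStack(
        frames=frames,
        frame_axis="echo_time_ms",
        frame_values=tuple(te),
        protocol=protocol,
        grid=phantom.grid,
        provenance={"noise_sigma_abs": sigma},
    )


def resample_nearest(field: np.ndarray, src_grid: Grid, dst_grid: Grid) -> np.ndarray:
    """Nearest-neighbour sample of a per-voxel field onto another grid.

    Both grids share the FOV centre (the MRE FOV is a centred crop of the
    phantom FOV), so piecewise-constant regions stay piecewise constant.
    """
    ym, xm = dst_grid.centers_mm()
    h = src_grid.spacing_mm
    iy = np.clip(np.round(ym / h + src_grid.ny / 2 - 0.5).astype(int), 0, src_grid.ny - 1)
    ix = np.clip(np.round(xm / h + src_grid.nx / 2 - 0.5).astype(int), 0, src_grid.nx - 1)
    return field[iy, ix]


def sample_modulus_on_grid(phantom: Phantom, mre_grid: Grid) -> np.ndarray:
    """Nearest-neighbour sample of the phantom's G* field on the MRE grid."""
    return resample_nearest(phantom.g_complex_pa, phantom.grid, mre_grid)


def simulate_mre_wavefield(
    phantom: Phantom,
    protocol: AcquisitionProtocol,
    direction: str = "x",
    amplitude_m: float = 2e-5,
    mre_grid: Grid = MRE_GRID,
    density_kg_m3: float = models.TISSUE_DENSITY_KG_M3,
) -> SignalStack:
    """Plane shear wave snapshots at equally spaced wave phases.

    The wave propagates along ``direction`` ('x' or 'y') through the
    piecewise-constant modulus field, accumulating local phase
    ``k(x) = omega * sqrt(rho / G*(x))`` voxel by voxel; within every
    homogeneous region the field is an exact Helmholtz solution, which the
    inversion relies on.  Snapshots are ``Re[v(x) * exp(i * theta_j)]`` at
    ``n_wave_phases`` phase offsets; identical in-plane fields are replicated
    over the thin slice stack.

    Raises when the local wavelength falls below four voxels (undersampled
    wave, cannot be inverted with central differences).
    """
    if protocol.modality != "MRE":
        raise ValueError("protocol modality must be MRE")
    if direction not in ("x", "y"):
        raise ValueError("direction must be 'x' or 'y'")
    g = sample_modulus_on_grid(phantom, mre_grid)
    k = models.shear_wavenumber(g, protocol.mre_frequency_hz, density_kg_m3)
    h_m = mre_grid.spacing_mm * 1e-3
    wavelength = 2.0 * np.pi / np.abs(k.real)
    if np.any(wavelength < 4.0 * h_m):
        raise ValueError("shear wavelength below 4 voxels: wave is undersampled")

    axis = 1 if direction == "x" else 0
    # cumulative phase along the propagation axis, exact for piecewise-
    # constant k: phi_i = sum_{j<=i} k_j*h - k_i*h/2  (voxel-centre sampling)
    phi = np.cumsum(k * h_m, axis=axis) - k * h_m / 2.0
    v = amplitude_m * np.exp(-1j * phi)
    v3d = np.broadcast_to(v, (mre_grid.n_slices,) + v.shape).copy()

    n = protocol.n_wave_phases
    thetas = 2.0 * np.pi * np.arange(n) / n
    frames = np.real(v3d[None] * np.exp(1j * thetas)[:, None, None, None])
    if protocol.noise_sigma > 0:
        rng = _rng(protocol)
        frames = frames + rng.normal(0.0, protocol.noise_sigma * amplitude_m, size=frames.shape)
    return SignalStack(
        frames=frames,
        frame_axis="wave_phase_rad",
        frame_values=tuple(thetas),
        protocol=protocol,
        grid=mre_grid,
        provenance={
            "direction": direction,
            "amplitude_m": amplitude_m,
            "density_kg_m3": density_kg_m3,
        },
    )
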