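"""MR elastography reconstruction: harmonic extraction + Helmholtz inversion.

The multi-phase displacement snapshots are reduced to a complex wave image by
a temporal discrete Fourier transform at the fundamental of the phase-offset
series, and the complex shear modulus is recovered voxelwise by direct
algebraic inversion of the Helmholtz equation::

    G* = -rho * omega^2 * u / laplacian(u)

with a second-order central-difference Laplacian.  The synthetic wavefields
are pure shear by construction, so no curl/compressional decomposition is
applied; this is a documented simplification relative to full reconstruction
pipelines used on scanner data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .fitting import ParametricMap
from .grid import Grid
from .models import TISSUE_DENSITY_KG_M3
from .simulate import SignalStack

#: voxels where |laplacian| falls below this fraction of its ROI median are
#: masked (wave nodes: the algebraic quotient blows up there)
LAPLACIAN_THRESHOLD_REL = 1e-3


@dataclass(frozen=True)
class ComplexWaveImage:
    """Complex displacement amplitude (m) at one mechanical frequency."""

    amplitude: np.ndarray  # (n_slices, ny, nx) complex
    frequency_hz: float
    grid: Grid

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be positive")
        if not np.all(np.isfinite(self.amplitude)):
            raise ValueError("amplitude must be finite")
        if self.amplitude.ndim != 3:
            raise ValueError("amplitude must be (n_slices, ny, nx)")


def extract_harmonic(stack: SignalStack) -> ComplexWaveImage:
    """Fundamental Fourier coefficient of the wave-phase series, per voxel.

    For snapshots ``u_j = Re[v * exp(i * theta_j)]`` at N >= 3 equally spaced
    phases, ``(2/N) * sum_j u_j * exp(-i * theta_j)`` returns ``v`` exactly;
    any DC offset is orthogonal to the fundamental and drops out.
    """
    if stack.protocol.modality != "MRE":
        raise ValueError("stack modality must be MRE")
    thetas = np.asarray(stack.frame_values, dtype=float)
    n = thetas.size
    if n < 3:
        raise ValueError("need >= 3 wave phases")
    spacing = np.diff(thetas)
    if not np.allclose(spacing, spacing[0]):
        raise ValueError("wave phases must be equally spaced")
    weights = np.exp(-1j * thetas)
    amp = (2.0 / n) * np.tensordot(weights, stack.frames, axes=(0, 0))
    return ComplexWaveImage(
        amplitude=amp, frequency_hz=stack.protocol.mre_frequency_hz, grid=stack.grid
    )


def _laplacian_2d(u: np.ndarray, h_m: float) -> np.ndarray:
    lap = np.full_like(u, np.nan)
    lap[:, 1:-1, 1:-1] = (
        u[:, 2:, 1:-1] + u[:, :-2, 1:-1] + u[:, 1:-1, 2:] + u[:, 1:-1, :-2]
        - 4.0 * u[:, 1:-1, 1:-1]
    ) / h_m**2
    return lap


def _laplacian_3d(u: np.ndarray, h_m: float, hz_m: float) -> np.ndarray:
    if u.shape[0] < 3:
        raise ValueError("3D Laplacian needs >= 3 slices")
    lap = np.full_like(u, np.nan)
    lap[1:-1, 1:-1, 1:-1] = (
        (u[1:-1, 2:, 1:-1] + u[1:-1, :-2, 1:-1] - 2 * u[1:-1, 1:-1, 1:-1]) / h_m**2
        + (u[1:-1, 1:-1, 2:] + u[1:-1, 1:-1, :-2] - 2 * u[1:-1, 1:-1, 1:-1]) / h_m**2
        + (u[2:, 1:-1, 1:-1] + u[:-2, 1:-1, 1:-1] - 2 * u[1:-1, 1:-1, 1:-1]) / hz_m**2
    )
    return lap


def invert_helmholtz(
    wave: ComplexWaveImage,
    density_kg_m3: float = TISSUE_DENSITY_KG_M3,
    laplacian: str = "2d",
    smooth_sigma_voxels: float = 0.0,
    roi: np.ndarray | None = None,
    lap_threshold_rel: float = LAPLACIAN_THRESHOLD_REL,
) -> tuple[ParametricMap, ParametricMap]:
    """Recover storage (G_d) and loss (G_l) modulus maps in kPa.

    Per voxel ``G* = -rho * omega^2 * u / laplacian(u)``; ``G_d = Re(G*)``,
    ``G_l = Im(G*)``.  A one-voxel rim (and, for the 3D Laplacian, the outer
    slices) is masked, as are wave nodes (|laplacian| below
    ``lap_threshold_rel`` times its ROI median) and voxels with a
    non-positive recovered storage modulus.  Optional Gaussian pre-smoothing
    (``smooth_sigma_voxels``) is off by default.
    """
    if density_kg_m3 <= 0:
        raise ValueError("density must be positive")
    if laplacian not in ("2d", "3d"):
        raise ValueError("laplacian must be '2d' or '3d'")
    u = wave.amplitude.astype(complex)
    if laplacian == "3d" and u.shape[0] < 3:
        raise ValueError("3D Laplacian requested on fewer than 3 slices")
    if smooth_sigma_voxels > 0:
        sig = (0.0, smooth_sigma_voxels, smooth_sigma_voxels)
        u = gaussian_filter(u.real, sig) + 1j * gaussian_filter(u.imag, sig)

    h_m = wave.grid.spacing_mm * 1e-3
    hz_m = wave.grid.slice_thickness_mm * 1e-3
    lap = _laplacian_2d(u, h_m) if laplacian == "2d" else _laplacian_3d(u, h_m, hz_m)

    omega = 2.0 * np.pi * wave.frequency_hz
    with np.errstate(divide="ignore", invalid="ignore"):
        g = -density_kg_m3 * omega**2 * u / lap

    lap_mag = np.abs(lap)
    finite = np.isfinite(lap_mag)
    sel = finite if roi is None else finite & np.broadcast_to(roi, lap_mag.shape)
    threshold = lap_threshold_rel * (np.median(lap_mag[sel]) if sel.any() else 0.0)
    valid = finite & (lap_mag > threshold) & np.isfinite(g) & (g.real > 0)

    gd = np.where(valid, g.real, np.nan) / 1e3
    gl = np.where(valid, g.imag, np.nan) / 1e3
    prov = {
        "method": "algebraic helmholtz",
        "laplacian": laplacian,
        "density_kg_m3": density_kg_m3,
        "smooth_sigma_voxels": smooth_sigma_voxels,
    }
    return (
        ParametricMap(gd, "kPa", valid, wave.grid, {**prov, "parameter": "G_d"}),
        ParametricMap(gl, "kPa", valid, wave.grid, {**prov, "parameter": "G_l"}),
    )
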