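"""Digital tumour phantoms.

A phantom is a set of per-voxel ground-truth tissue parameter fields on the
quantitative-map grid: relaxation times T1/T2 (ms), fractional magnetisation
transfer attenuation, ADC (1e-6 mm^2/s), R2* (1/s), the complex shear modulus
G* = G_d + i*G_l (Pa), a unitless proton density, a necrosis mask and a
hyaluronan (HA) volume-fraction field.

Phantoms are built from a recipe: an ordered list of elliptical regions that
tile a tumour ellipse inside a background of default tissue, each carrying
the parameter values to paint.  Overlapping regions with contradictory
parameter values are an error unless the later region is explicitly marked
as an override.  Optional multiplicative smooth heterogeneity is applied per
field, seeded, so every phantom is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .grid import Grid, MRI_GRID

#: parameter keys a region may paint, with background defaults emulating
#: peritumoural soft tissue (muscle/fat mixture at 7 T)
BACKGROUND_DEFAULTS: dict[str, float] = {
    "t1_ms": 1100.0,
    "t2_ms": 30.0,
    "mt_attenuation": 0.45,
    "adc": 1400.0,
    "r2star_s": 40.0,
    "g_d_kpa": 8.0,
    "g_l_kpa": 3.0,
    "proton_density": 0.7,
    "ha_density": 0.0,
}

#: fields that never receive heterogeneity or may need clipping to [0, 1]
_UNIT_INTERVAL_FIELDS = ("mt_attenuation", "ha_density")


@dataclass(frozen=True)
class Region:
    """One elliptical recipe region.

    ``center`` and ``radii`` are fractions of the FOV, so recipes are grid
    independent.  ``necrotic`` marks the painted voxels in the necrosis mask;
    ``override`` allows painting over previously painted voxels with
    different parameter values.
    """

    name: str
    center: tuple[float, float]  # (y, x) as FOV fractions, 0.5 = centre
    radii: tuple[float, float]  # (ry, rx) as FOV fractions
    params: dict[str, float] = field(default_factory=dict)
    necrotic: bool = False
    override: bool = False

    def mask(self, grid: Grid) -> np.ndarray:
        yy, xx = np.meshgrid(
            (np.arange(grid.ny) + 0.5) / grid.ny,
            (np.arange(grid.nx) + 0.5) / grid.nx,
            indexing="ij",
        )
        return ((yy - self.center[0]) / self.radii[0]) ** 2 + (
            (xx - self.center[1]) / self.radii[1]
        ) ** 2 <= 1.0


@dataclass(frozen=True)
class PhantomRecipe:
    """Recipe for :func:`make_phantom`; regions are painted in order."""

    regions: tuple[Region, ...]
    grid: Grid = MRI_GRID
    heterogeneity: float = 0.0  # fractional sd of the smooth multiplicative field
    smooth_voxels: float = 3.0  # Gaussian correlation length of that field
    seed: int = 0


@dataclass(frozen=True)
class Phantom:
    """Ground-truth tissue parameter fields on one axial slice."""

    t1_ms: np.ndarray
    t2_ms: np.ndarray
    mt_attenuation: np.ndarray
    adc: np.ndarray
    r2star_s: np.ndarray
    g_complex_pa: np.ndarray
    proton_density: np.ndarray
    necrosis_mask: np.ndarray
    ha_density: np.ndarray
    tumour_mask: np.ndarray
    grid: Grid = MRI_GRID

    def __post_init__(self) -> None:
        shape = self.grid.shape
        for name in (
            "t1_ms", "t2_ms", "mt_attenuation", "adc", "r2star_s",
            "g_complex_pa", "proton_density", "necrosis_mask", "ha_density",
            "tumour_mask",
        ):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape does not match grid {shape}")
        if np.any(self.t1_ms <= 0) or np.any(self.t2_ms <= 0):
            raise ValueError("relaxation times must be positive")
        if np.any(self.adc < 0):
            raise ValueError("ADC must be non-negative")
        if np.any((self.mt_attenuation < 0) | (self.mt_attenuation > 1)):
            raise ValueError("mt_attenuation must lie in [0, 1]")
        if np.any((self.ha_density < 0) | (self.ha_density > 1)):
            raise ValueError("ha_density must lie in [0, 1]")
        if np.any(self.g_complex_pa.real <= 0) or np.any(self.g_complex_pa.imag < 0):
            raise ValueError("shear modulus must have Re > 0 and Im >= 0")

    @property
    def viable_mask(self) -> np.ndarray:
        """Viable-tumour ROI: tumour voxels excluding necrosis."""
        return self.tumour_mask & ~self.necrosis_mask

    def with_fields(self, **updates: np.ndarray) -> "Phantom":
        return replace(self, **updates)


def tumour_recipe(
    params: dict[str, float],
    necrotic_core: dict[str, float] | None = None,
    tumour_radii: tuple[float, float] = (0.32, 0.28),
    core_radius: float = 0.10,
    heterogeneity: float = 0.0,
    smooth_voxels: float = 3.0,
    grid: Grid = MRI_GRID,
    seed: int = 0,
) -> PhantomRecipe:
    """Convenience recipe: one tumour ellipse, optionally with a necrotic core.

    ``params`` are viable-tumour values (keys of :data:`BACKGROUND_DEFAULTS`);
    ``necrotic_core`` gives the core's overriding values (necrotic tissue has
    longer T2, higher ADC and low proton turnover).
    """
    regions = [
        Region(name="viable", center=(0.5, 0.5), radii=tumour_radii, params=dict(params))
    ]
    if necrotic_core is not None:
        regions.append(
            Region(
                name="core",
                center=(0.5, 0.5),
                radii=(core_radius, core_radius),
                params=dict(necrotic_core),
                necrotic=True,
                override=True,
            )
        )
    return PhantomRecipe(
        regions=tuple(regions),
        grid=grid,
        heterogeneity=heterogeneity,
        smooth_voxels=smooth_voxels,
        seed=seed,
    )


def _smooth_noise(shape, sigma, rng) -> np.ndarray:
    """Unit-variance smooth Gaussian field (correlation length sigma voxels)."""
    raw = rng.standard_normal(shape)
    if sigma <= 0:
        return raw
    sm = gaussian_filter(raw, sigma, mode="nearest")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def make_phantom(recipe: PhantomRecipe) -> Phantom:
    """Paint a recipe into ground-truth fields.

    Raises ``ValueError`` when two regions overlap with contradictory
    parameter values and the later one is not an override.
    """
    grid = recipe.grid
    rng = np.random.default_rng(recipe.seed)
    fields = {k: np.full(grid.shape, v, dtype=float) for k, v in BACKGROUND_DEFAULTS.items()}
    painted = np.zeros(grid.shape, dtype=bool)
    necrosis = np.zeros(grid.shape, dtype=bool)
    tumour = np.zeros(grid.shape, dtype=bool)

    for region in recipe.regions:
        unknown = set(region.params) - set(BACKGROUND_DEFAULTS)
        if unknown:
            raise ValueError(f"region {region.name!r}: unknown parameters {sorted(unknown)}")
        mask = region.mask(grid)
        overlap = mask & painted
        if overlap.any() and not region.override:
            contradictory = any(
                not np.allclose(fields[k][overlap], v) for k, v in region.params.items()
            )
            if contradictory:
                raise ValueError(
                    f"region {region.name!r} overlaps an earlier region with "
                    "contradictory parameters (set override=True to paint over)"
                )
        for k, v in region.params.items():
            fields[k][mask] = v
        painted |= mask
        tumour |= mask
        if region.necrotic:
            necrosis[mask] = True

    if recipe.heterogeneity > 0:
        for k in fields:
            if k in _UNIT_INTERVAL_FIELDS:
                noise = _smooth_noise(grid.shape, recipe.smooth_voxels, rng)
                fields[k] = np.clip(fields[k] * (1.0 + recipe.heterogeneity * noise), 0.0, 1.0)
            else:
                noise = _smooth_noise(grid.shape, recipe.smooth_voxels, rng)
                fields[k] = fields[k] * np.clip(1.0 + recipe.heterogeneity * noise, 0.05, None)

    g_complex = (fields["g_d_kpa"] + 1j * np.clip(fields["g_l_kpa"], 0.0, None)) * 1e3
    return Phantom(
        t1_ms=fields["t1_ms"],
        t2_ms=fields["t2_ms"],
        mt_attenuation=fields["mt_attenuation"],
        adc=fields["adc"],
        r2star_s=fields["r2star_s"],
        g_complex_pa=g_complex,
        proton_density=fields["proton_density"],
        necrosis_mask=necrosis,
        ha_density=fields["ha_density"],
        tumour_mask=tumour,
        grid=grid,
    )
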