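"""Voxel geometry shared by phantoms, signal stacks and parametric maps.

All in-plane grids are square fields of view sampled at voxel centres with
0-based indices; the axial (slice) direction is handled separately because the
quantitative maps use a single 1 mm slice while elastography uses three
0.3 mm slices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Grid:
    """In-plane voxel geometry of an axial acquisition.

    Parameters
    ----------
    nx, ny:
        Matrix size (columns, rows).  Fields of view are square, so the
        in-plane spacing is ``fov_mm / nx`` and ``nx == ny`` is required.
    fov_mm:
        In-plane field of view (mm).
    slice_thickness_mm:
        Axial slice thickness (mm).
    n_slices:
        Number of contiguous axial slices.
    """

    nx: int
    ny: int
    fov_mm: float
    slice_thickness_mm: float = 1.0
    n_slices: int = 1

    def __post_init__(self) -> None:
        if self.nx <= 0 or self.ny <= 0:
            raise ValueError("matrix size must be positive")
        if self.nx != self.ny:
            raise ValueError("square matrix required for a square FOV")
        if self.fov_mm <= 0:
            raise ValueError("fov_mm must be positive")
        if self.slice_thickness_mm <= 0:
            raise ValueError("slice_thickness_mm must be positive")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")

    @property
    def spacing_mm(self) -> float:
        """In-plane voxel spacing (mm); equals FOV / matrix by construction."""
        return self.fov_mm / self.nx

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) array shape of one slice."""
        return (self.ny, self.nx)

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing_mm**2 * self.slice_thickness_mm

    def centers_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Voxel-centre coordinates (y, x) in mm, origin at the FOV centre."""
        h = self.spacing_mm
        x = (np.arange(self.nx) + 0.5) * h - self.fov_mm / 2.0
        y = (np.arange(self.ny) + 0.5) * h - self.fov_mm / 2.0
        return np.meshgrid(y, x, indexing="ij")

    def compatible(self, other: "Grid", rtol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.isclose(
            self.spacing_mm, other.spacing_mm, rtol=rtol
        )


#: default quantitative-map grid: 128 x 128 over a 3 x 3 cm FOV, 1 mm slice
MRI_GRID = Grid(nx=128, ny=128, fov_mm=30.0, slice_thickness_mm=1.0, n_slices=1)

#: default elastography grid: 64 x 64 over 1.92 x 1.92 cm, three 0.3 mm slices
MRE_GRID = Grid(nx=64, ny=64, fov_mm=19.2, slice_thickness_mm=0.3, n_slices=3)
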