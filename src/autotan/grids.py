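"""Voxel lattice container shared by density, masks and dose.

Coordinates are a patient-LPS-like right-handed frame in millimetres:
x toward the patient's left, y posterior, z superior.  Voxel indexing is
0-based and a voxel (i, j, k) is the half-open box
``[origin + i*spacing, origin + (i+1)*spacing)``; its centre sits at
``origin + (i + 0.5) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class VoxelGrid:
    """A scalar field on a regular 3D lattice.

    Parameters
    ----------
    origin : (3,) array-like, mm
        Physical position of the corner of voxel (0, 0, 0).
    spacing : (3,) array-like, mm
        Per-axis voxel size; strictly positive.
    values : ndarray
        Per-voxel scalars; shape defines ``dims``.  Units are owned by the
        user of the grid (g/cm^3 for density, Gy for dose, bool for masks).
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.origin.shape != (3,) or self.spacing.shape != (3,):
            raise ValueError("origin and spacing must be 3-vectors")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive on all axes")
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("values must be a non-empty 3D array")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def same_lattice(self, other: "VoxelGrid") -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.origin, other.origin)
            and np.allclose(self.spacing, other.spacing)
        )

    def like(self, values: np.ndarray) -> "VoxelGrid":
        """New grid on this lattice holding ``values``."""
        return VoxelGrid(self.origin.copy(), self.spacing.copy(), values)

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(self.origin.copy(), self.spacing.copy(), self.values.copy())

    # --- geometry helpers -------------------------------------------------

    def axis_centers(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates along one axis, mm."""
        n = self.dims[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable voxel-centre coordinate arrays (X, Y, Z), mm."""
        cx = self.axis_centers(0)[:, None, None]
        cy = self.axis_centers(1)[None, :, None]
        cz = self.axis_centers(2)[None, None, :]
        return cx, cy, cz

    def points_mm(self, flat_index: np.ndarray) -> np.ndarray:
        """(N, 3) voxel-centre world coordinates for flat C-order indices."""
        ijk = np.stack(np.unravel_index(flat_index, self.dims), axis=-1)
        return self.origin + (ijk + 0.5) * self.spacing

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel-centre index coordinates of points."""
        return (np.asarray(points_mm, dtype=float) - self.origin) / self.spacing - 0.5

    def bbox_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical bounding box (lower corner, upper corner), mm."""
        lo = self.origin
        hi = self.origin + np.asarray(self.dims) * self.spacing
        return lo, hi


def mask_volume_cm3(mask: VoxelGrid) -> float:
    """Volume of a binary mask in cm^3 by voxel counting."""
    return float(np.count_nonzero(mask.values)) * mask.voxel_volume_cm3


@dataclass
class BEVMap:
    """A 2D raster in the beam's-eye-view at the isocenter plane.

    ``u`` is the leaf-travel axis with +u toward the anterior field border,
    ``v`` runs inferior->superior; both in cm at isocenter scale.  Pixel
    (iu, iv) covers ``[u0 + iu*pixel_cm, u0 + (iu+1)*pixel_cm)`` etc.
    """

    u0: float
    v0: float
    pixel_cm: float
    values: np.ndarray  # (nu, nv)

    def u_centers(self) -> np.ndarray:
        return self.u0 + (np.arange(self.values.shape[0]) + 0.5) * self.pixel_cm

    def v_centers(self) -> np.ndarray:
        return self.v0 + (np.arange(self.values.shape[1]) + 0.5) * self.pixel_cm
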