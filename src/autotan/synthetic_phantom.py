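"""Reproducible voxel breast phantoms.

A phantom is a thorax (elliptical cylinder of water-equivalent tissue)
containing two low-density lungs and a left-sided heart, with a convex
half-ellipsoidal breast protruding from the antero-lateral chest wall on
the configured side.  It stands in for the CT simulation data of a
whole-breast radiotherapy patient: open tangential beams across the
chest wall produce the anterior breast hotspot that the field-in-field
planning workflow is designed to remove.

All randomness (the optional breast surface noise) flows from the config
seed; building the same config twice yields voxel-identical phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .grids import VoxelGrid

MAX_VOXELS = 10**8  # resource guard

DENSITY_WATER = 1.0  # g/cm^3, body / breast / heart surrogate


@dataclass
class PhantomConfig:
    """Geometry and material parameters of one synthetic phantom.

    Lengths in mm, densities in g/cm^3.  ``breast_angle_deg`` locates the
    breast base centre on the thorax surface, measured from the anterior
    midline toward the ipsilateral side.
    """

    spacing_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    extent_mm: tuple[float, float, float] = (300.0, 300.0, 150.0)
    thorax_semi_axes_mm: tuple[float, float] = (130.0, 85.0)  # (x, y)
    thorax_center_mm: tuple[float, float] = (0.0, 25.0)
    breast_base_radius_mm: float = 60.0
    breast_height_mm: float = 55.0
    breast_angle_deg: float = 40.0
    laterality: str = "left"
    lung_density: float = 0.26
    lung_semi_axes_mm: tuple[float, float, float] = (45.0, 62.0, 65.0)
    lung_center_offset_mm: tuple[float, float, float] = (55.0, 0.0, 0.0)
    heart_center_offset_mm: tuple[float, float, float] = (35.0, -10.0, -25.0)
    heart_radius_mm: float = 40.0
    surface_noise_mm: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        lengths = (
            *self.spacing_mm,
            *self.extent_mm,
            *self.thorax_semi_axes_mm,
            self.breast_base_radius_mm,
            self.breast_height_mm,
            *self.lung_semi_axes_mm,
            self.heart_radius_mm,
        )
        if any(v <= 0 for v in lengths):
            raise ValueError("all lengths must be positive")
        if self.laterality not in ("left", "right"):
            raise ValueError("laterality must be 'left' or 'right'")
        if self.surface_noise_mm < 0:
            raise ValueError("surface noise amplitude must be >= 0")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")


@dataclass
class Phantom:
    """Density grid plus named binary structure masks on a shared lattice."""

    density: VoxelGrid
    masks: dict[str, VoxelGrid]
    laterality: str
    config: PhantomConfig | None = None
    meta: dict = field(default_factory=dict)

    REQUIRED_MASKS = ("body", "breast", "lung_ipsi", "lung_contra", "heart")

    def mask(self, name: str) -> VoxelGrid:
        return self.masks[name]

    def validate(self) -> None:
        for name in self.REQUIRED_MASKS:
            if name not in self.masks:
                raise ValueError(f"missing mask {name!r}")
            if not self.masks[name].same_lattice(self.density):
                raise ValueError(f"mask {name!r} not on the density lattice")
        body = self.masks["body"].values
        breast = self.masks["breast"].values
        if np.any(breast & ~body):
            raise ValueError("breast must be contained in body")
        if np.any(breast & self.masks["lung_ipsi"].values):
            raise ValueError("breast and ipsilateral lung must be disjoint")
        dens = self.density.values
        if dens.min() < 0 or dens.max() > 3.0:
            raise ValueError("density out of [0, 3] g/cm^3")


def _smooth_noise_field(shape, rng, amplitude_mm, spacing_mm):
    """Smooth zero-mean random field (mm units) for surface perturbation."""
    if amplitude_mm == 0:
        return np.zeros(shape)
    raw = rng.standard_normal(shape)
    # ~15 mm correlation length keeps the breast convex at low amplitude
    sigma_vox = [15.0 / s for s in spacing_mm]
    smooth = ndimage.gaussian_filter(raw, sigma=sigma_vox, mode="nearest")
    rms = np.sqrt(np.mean(smooth**2))
    return smooth * (amplitude_mm / max(rms, 1e-12))


def breast_frame(config: PhantomConfig):
    """Breast base point, outward normal and chest-wall tangent (axial).

    Returns ``(p0, n, t)`` in mm / unit vectors: ``p0`` is the breast base
    centre on the thorax surface, ``n`` the outward surface normal there,
    and ``t`` the in-plane tangent pointing postero-laterally (the
    direction along which tangential beams travel for the medial field).
    """
    ax, ay = config.thorax_semi_axes_mm
    cx, cy = config.thorax_center_mm
    lat = 1.0 if config.laterality == "left" else -1.0
    phi = np.deg2rad(config.breast_angle_deg)
    p0 = np.array([cx + lat * ax * np.sin(phi), cy - ay * np.cos(phi), 0.0])
    n = np.array([(p0[0] - cx) / ax**2, (p0[1] - cy) / ay**2, 0.0])
    n /= np.linalg.norm(n)
    t = np.array([lat * ax * np.cos(phi), ay * np.sin(phi), 0.0])
    t /= np.linalg.norm(t)
    return p0, n, t


def build_phantom(config: PhantomConfig) -> Phantom:
    """Build a deterministic voxel phantom from a config.

    Body = thorax union breast; lungs are filled with the configured low
    density (no noise inside lungs); the heart is a water-density sphere
    left of midline carved out of the left lung.
    """
    config.validate()
    spacing = np.asarray(config.spacing_mm, dtype=float)
    extent = np.asarray(config.extent_mm, dtype=float)
    dims = np.maximum(np.round(extent / spacing).astype(int), 1)
    if int(np.prod(dims)) > MAX_VOXELS:
        raise ValueError(
            f"grid of {int(np.prod(dims))} voxels exceeds the {MAX_VOXELS} guard"
        )
    origin = -extent / 2.0
    grid = VoxelGrid(origin, spacing, np.zeros(tuple(dims), dtype=np.float32))
    X, Y, Z = grid.center_mesh()

    ax, ay = config.thorax_semi_axes_mm
    cx, cy = config.thorax_center_mm
    thorax = ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 <= 1.0

    # --- breast: half-ellipsoid on the chest wall, axis along the local
    # outward normal; the shallow gap left by chest-wall curvature under
    # the base plane is filled down to the thorax surface.
    p0, n, t = breast_frame(config)
    a = config.breast_base_radius_mm
    h = config.breast_height_mm
    c = config.breast_base_radius_mm  # circular base in the tangent plane
    dx, dy, dz = X - p0[0], Y - p0[1], Z - p0[2]
    xi = dx * t[0] + dy * t[1]
    eta = dx * n[0] + dy * n[1]
    zeta = dz
    rng = np.random.default_rng(int(config.seed))
    noise = _smooth_noise_field(grid.dims, rng, config.surface_noise_mm, spacing)
    r_scale = (a + h + c) / 3.0
    r = np.sqrt((xi / a) ** 2 + (eta / h) ** 2 + (zeta / c) ** 2)
    half_ellipsoid = (r <= 1.0 + noise / r_scale) & (eta >= 0)
    gap_fill = (
        (eta < 0)
        & (eta >= -40.0)
        & ((xi / a) ** 2 + (zeta / c) ** 2 <= 1.0)
    )
    breast = (half_ellipsoid | gap_fill) & ~thorax
    body = thorax | breast

    lat = 1.0 if config.laterality == "left" else -1.0
    lx, ly, lz = config.lung_semi_axes_mm
    ox, oy, oz = config.lung_center_offset_mm

    def lung(side: float) -> np.ndarray:
        return (
            ((X - (cx + side * ox)) / lx) ** 2
            + ((Y - (cy + oy)) / ly) ** 2
            + ((Z - oz) / lz) ** 2
        ) <= 1.0

    hx, hy, hz = config.heart_center_offset_mm
    heart = (
        (X - (cx + hx)) ** 2 + (Y - (cy + hy)) ** 2 + (Z - hz) ** 2
        <= config.heart_radius_mm**2
    ) & thorax

    lung_left = lung(+1.0) & thorax & ~heart
    lung_right = lung(-1.0) & thorax & ~heart
    lung_ipsi = lung_left if lat > 0 else lung_right
    lung_contra = lung_right if lat > 0 else lung_left

    density = np.zeros(grid.dims, dtype=np.float32)
    density[body] = DENSITY_WATER
    density[lung_left | lung_right] = config.lung_density

    def as_mask(arr: np.ndarray) -> VoxelGrid:
        return grid.like(arr)

    phantom = Phantom(
        density=grid.like(density),
        masks={
            "body": as_mask(body),
            "breast": as_mask(breast),
            "lung_ipsi": as_mask(lung_ipsi),
            "lung_contra": as_mask(lung_contra),
            "heart": as_mask(heart),
        },
        laterality=config.laterality,
        config=config,
        meta={"base_point_mm": p0, "base_normal": n, "base_tangent": t},
    )
    phantom.validate()
    return phantom


def default_phantom_suite(n: int, seed: int = 0) -> list[Phantom]:
    """Deterministic suite of ``n`` phantoms varying breast size/side.

    Breast base radius spans 50-72 mm monotonically across the suite,
    height scales with radius, laterality alternates starting left, and
    each phantom gets 1 mm surface noise seeded from ``seed``.  ``n=1``
    returns exactly the default phantom.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        return [build_phantom(PhantomConfig(seed=int(seed)))]
    radii = np.linspace(50.0, 72.0, n)
    phantoms = []
    for i, radius in enumerate(radii):
        cfg = PhantomConfig(
            breast_base_radius_mm=float(radius),
            breast_height_mm=float(0.9 * radius),
            laterality="left" if i % 2 == 0 else "right",
            surface_noise_mm=1.0,
            seed=(int(seed) * 10007 + i) % 2**31,
        )
        phantoms.append(build_phantom(cfg))
    return phantoms
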