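"""Voxel phantoms and structure masks.

Coordinate convention used throughout the package: the beam axis at gantry 0
points along +z ("depth"); the phantom entrance surface for that beam is the
z = 0 plane, and the source sits at z = -SSD.  Voxel grids are indexed
``[ix, iy, iz]`` with half-open voxel extents [lo, hi); the voxel center of
index i along an axis is ``origin + (i + 0.5) * voxel_size``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .materials import DEFAULT_DENSITIES

__all__ = [
    "PhantomSpec",
    "VoxelPhantom",
    "StructureSet",
    "generate_phantom",
    "water_cube",
    "soft_tissue_cube",
    "cranium_slab_phantom",
    "femur_block_phantom",
    "planning_phantom",
    "save_volume",
    "load_volume",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative phantom description: extents, voxel size, painted regions.

    ``material_regions`` is an ordered list of (geometry, material name,
    density g/cm^3); geometries are dicts, e.g.
    ``{"type": "all"}``,
    ``{"type": "box", "lo": (x,y,z), "hi": (x,y,z)}``,
    ``{"type": "sphere", "center": (x,y,z), "radius": r}``,
    ``{"type": "ellipsoid", "center": (x,y,z), "semi_axes": (a,b,c)}``.
    Later regions overwrite earlier ones (last painted wins; overlaps are
    logged as warnings).
    """

    extent: tuple[float, float, float]  # cm
    voxel_size: tuple[float, float, float]  # cm
    material_regions: tuple[tuple[dict, str, float], ...]
    origin: tuple[float, float, float] | None = None  # low corner, cm

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        if any(e <= 0 for e in self.extent):
            raise ValueError("extent must be positive")
        for _, _, rho in self.material_regions:
            if rho <= 0:
                raise ValueError("densities must be positive")


@dataclass
class VoxelPhantom:
    """Density grid plus a parallel material-index grid."""

    density: np.ndarray  # g/cm^3, shape (nx, ny, nz)
    voxel_size: np.ndarray  # (3,), cm
    origin: np.ndarray  # (3,), low corner, cm
    material_index: np.ndarray | None = None  # int8 grid into material_names
    material_names: list[str] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.density.shape

    @property
    def upper(self) -> np.ndarray:
        return self.origin + self.voxel_size * np.array(self.shape)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_size[axis]

    def center_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.meshgrid(self.centers(0), self.centers(1), self.centers(2), indexing="ij")

    @property
    def mass(self) -> float:
        """Total mass in grams."""
        return float(self.density.sum() * self.voxel_volume)


StructureSet = dict[str, np.ndarray]


def _region_mask(geom: dict, xx: np.ndarray, yy: np.ndarray, zz: np.ndarray) -> np.ndarray:
    kind = geom["type"]
    if kind == "all":
        return np.ones(xx.shape, dtype=bool)
    if kind == "box":
        lo, hi = np.asarray(geom["lo"], float), np.asarray(geom["hi"], float)
        return ((xx >= lo[0]) & (xx < hi[0]) & (yy >= lo[1]) & (yy < hi[1])
                & (zz >= lo[2]) & (zz < hi[2]))
    if kind == "sphere":
        c = np.asarray(geom["center"], float)
        r = float(geom["radius"])
        return (xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2 <= r**2
    if kind == "ellipsoid":
        c = np.asarray(geom["center"], float)
        a = np.asarray(geom["semi_axes"], float)
        return (((xx - c[0]) / a[0]) ** 2 + ((yy - c[1]) / a[1]) ** 2
                + ((zz - c[2]) / a[2]) ** 2) <= 1.0
    raise ValueError(f"unknown region geometry {kind!r}")


def generate_phantom(spec: PhantomSpec) -> VoxelPhantom:
    """Paint a voxel phantom from a PhantomSpec (voxel-center membership)."""
    vox = np.asarray(spec.voxel_size, float)
    shape = tuple(int(round(e / v)) for e, v in zip(spec.extent, vox))
    origin = (np.asarray(spec.origin, float) if spec.origin is not None
              else np.array([-0.5 * spec.extent[0], -0.5 * spec.extent[1], 0.0]))
    density = np.zeros(shape, dtype=np.float64)
    mat_index = np.full(shape, -1, dtype=np.int8)
    names: list[str] = []
    xs = origin[0] + (np.arange(shape[0]) + 0.5) * vox[0]
    ys = origin[1] + (np.arange(shape[1]) + 0.5) * vox[1]
    zs = origin[2] + (np.arange(shape[2]) + 0.5) * vox[2]
    xx, yy, zz = np.meshgrid(xs, ys, zs, indexing="ij")
    painted = np.zeros(shape, dtype=bool)
    for geom, material, rho in spec.material_regions:
        mask = _region_mask(geom, xx, yy, zz)
        overlap = mask & painted
        if overlap.any() and geom["type"] != "all":
            log.warning("region %r (%s) overwrites %d previously painted voxels "
                        "(last painted wins)", geom["type"], material, int(overlap.sum()))
        if material in names:
            idx = names.index(material)
        else:
            names.append(material)
            idx = len(names) - 1
        density[mask] = rho
        mat_index[mask] = idx
        painted |= mask
    return VoxelPhantom(density=density, voxel_size=vox, origin=origin,
                        material_index=mat_index, material_names=names)


# ----------------------------- presets --------------------------------------

def water_cube(extent: float = 50.0, voxel: float = 0.5) -> VoxelPhantom:
    """Homogeneous water cube, entrance surface at z = 0."""
    spec = PhantomSpec(
        extent=(extent, extent, extent), voxel_size=(voxel, voxel, voxel),
        material_regions=((({"type": "all"}), "water", DEFAULT_DENSITIES["water"]),),
    )
    return generate_phantom(spec)


def soft_tissue_cube(extent: float = 50.0, voxel: float = 0.5) -> VoxelPhantom:
    spec = PhantomSpec(
        extent=(extent, extent, extent), voxel_size=(voxel, voxel, voxel),
        material_regions=((({"type": "all"}), "soft_tissue", DEFAULT_DENSITIES["soft_tissue"]),),
    )
    return generate_phantom(spec)


def cranium_slab_phantom(extent: float = 50.0, voxel: float = 0.25) -> VoxelPhantom:
    """Soft-tissue cube with a 0.5 cm cranium-like bone layer at 1.5-2 cm depth."""
    half = 0.5 * extent
    spec = PhantomSpec(
        extent=(extent, extent, extent), voxel_size=(voxel, voxel, voxel),
        material_regions=(
            ({"type": "all"}, "soft_tissue", DEFAULT_DENSITIES["soft_tissue"]),
            ({"type": "box", "lo": (-half, -half, 1.5), "hi": (half, half, 2.0)},
             "cranium_bone", DEFAULT_DENSITIES["cranium_bone"]),
        ),
    )
    return generate_phantom(spec)


def femur_block_phantom(extent: float = 50.0, voxel: float = 0.25) -> VoxelPhantom:
    """Soft-tissue cube with a 4x4x4 cm^3 femur-like bone block at 4-8 cm depth."""
    spec = PhantomSpec(
        extent=(extent, extent, extent), voxel_size=(voxel, voxel, voxel),
        material_regions=(
            ({"type": "all"}, "soft_tissue", DEFAULT_DENSITIES["soft_tissue"]),
            ({"type": "box", "lo": (-2.0, -2.0, 4.0), "hi": (2.0, 2.0, 8.0)},
             "femur_bone", DEFAULT_DENSITIES["femur_bone"]),
        ),
    )
    return generate_phantom(spec)


def planning_phantom(
    target_depth: float = 4.0,
    voxel: float = 0.4,
    body_semi_axes: tuple[float, float, float] = (10.0, 10.0, 9.0),
    ptv_radius: float = 1.5,
) -> tuple[VoxelPhantom, StructureSet]:
    """Patient-like planning phantom: ellipsoidal water-equivalent body with a
    spherical PTV at ``target_depth`` below the anterior (z = 0-facing)
    surface and two organ-at-risk spheres (one lateral, one distal).

    Returns the phantom and a structure set with masks for body, ptv,
    oar_distal and oar_lateral.
    """
    a, b, c = body_semi_axes
    extent = (2.0 * a + 2.0, 2.0 * b + 2.0, 2.0 * c + 2.0)
    origin = (-0.5 * extent[0], -0.5 * extent[1], -1.0)
    center = (0.0, 0.0, c)  # body center; anterior surface near z = 0
    spec = PhantomSpec(
        extent=extent, voxel_size=(voxel, voxel, voxel), origin=origin,
        material_regions=(
            ({"type": "ellipsoid", "center": center, "semi_axes": (a, b, c)},
             "water", 1.0),
        ),
    )
    phantom = generate_phantom(spec)
    xx, yy, zz = phantom.center_grids()
    body = phantom.density > 0
    ptv_center = np.array([0.0, 0.0, target_depth])
    ptv = ((xx - ptv_center[0]) ** 2 + (yy - ptv_center[1]) ** 2
           + (zz - ptv_center[2]) ** 2) <= ptv_radius**2
    oar_distal_center = ptv_center + np.array([0.0, 0.0, ptv_radius + 2.5])
    oar_lateral_center = ptv_center + np.array([ptv_radius + 3.0, 0.0, 0.0])
    oar_r = 1.2
    oar_distal = ((xx - oar_distal_center[0]) ** 2 + (yy - oar_distal_center[1]) ** 2
                  + (zz - oar_distal_center[2]) ** 2) <= oar_r**2
    oar_lateral = ((xx - oar_lateral_center[0]) ** 2 + (yy - oar_lateral_center[1]) ** 2
                   + (zz - oar_lateral_center[2]) ** 2) <= oar_r**2
    structures: StructureSet = {
        "body": body,
        "ptv": ptv & body,
        "oar_distal": oar_distal & body,
        "oar_lateral": oar_lateral & body,
    }
    return phantom, structures


# --------------------------- volume file IO ---------------------------------

def save_volume(array: np.ndarray, voxel_size, origin, path: str | Path) -> Path:
    """Write a volumetric grid (density, mask or dose) as NIfTI."""
    path = Path(path)
    affine = np.diag([*np.asarray(voxel_size, float), 1.0])
    affine[:3, 3] = np.asarray(origin, float)
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float32), affine)
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns (array, voxel_size, origin)."""
    img = nib.load(str(path))
    affine = img.affine
    return (np.asarray(img.dataobj), np.diag(affine)[:3].copy(), affine[:3, 3].copy())
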