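"""Pencil-beam photon dose engine.

Per-beamlet dose in a voxel phantom from a commissioned BeamModel:

    dose = calibration * OF(eq. square) * TMR(d_rad, eq. square)
           * (SAD / source-voxel distance)^2 * intensity(off-axis radius)
           * sum_c w_c * BoxKernel_c(lateral offsets)

Heterogeneity is handled through the radiological depth d_rad (density-
weighted path length); dose is reported to water.  Lateral kernels are
evaluated in isocenter-plane coordinates, i.e. their physical widths scale
with the geometric magnification of the depth plane.  The erf-box beamlet
kernels form a partition of unity over the fluence lattice, so summing all
beamlets of an open field reproduces the commissioned TMR exactly on the
central axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.special import erf

from .commissioning import BeamModel, equivalent_square
from .phantoms import VoxelPhantom
from .raytrace import radiological_depth_grid

__all__ = [
    "BeamSetup",
    "InfluenceMatrix",
    "BeamGeometry",
    "beam_geometry",
    "beamlet_dose",
    "influence_matrix",
    "openfield_pdd",
    "openfield_profile",
    "aperture_equivalent_square",
]


@dataclass
class BeamSetup:
    """One treatment beam: orientation, isocenter and fluence lattice."""

    gantry_deg: float
    couch_deg: float = 0.0
    isocenter: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sad: float = 100.0
    bixel_width: float = 0.5  # cm at isocenter
    n_bixels: tuple[int, int] = (1, 1)  # lattice extent (crossplane, inplane)
    active: np.ndarray | None = None  # bool mask over the lattice

    def __post_init__(self) -> None:
        if not (0.0 <= self.gantry_deg < 360.0 and 0.0 <= self.couch_deg < 360.0):
            raise ValueError("angles must lie in [0, 360)")
        if self.bixel_width <= 0:
            raise ValueError("bixel width must be positive")
        if self.active is None:
            self.active = np.ones(self.n_bixels, dtype=bool)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(e_x, e_y, e_z): crossplane, inplane, beam direction unit vectors.

        IEC-style: gantry rotates about the phantom y axis, couch about z;
        at gantry = couch = 0 the beam travels along +z (into depth).
        """
        g = np.deg2rad(self.gantry_deg)
        c = np.deg2rad(self.couch_deg)
        ez = np.array([np.sin(g), 0.0, np.cos(g)])
        ex = np.array([np.cos(g), 0.0, -np.sin(g)])
        ey = np.array([0.0, 1.0, 0.0])
        rz = np.array([[np.cos(c), -np.sin(c), 0.0],
                       [np.sin(c), np.cos(c), 0.0],
                       [0.0, 0.0, 1.0]])
        return rz @ ex, rz @ ey, rz @ ez

    @property
    def source(self) -> np.ndarray:
        _, _, ez = self.axes()
        return np.asarray(self.isocenter, float) - self.sad * ez

    def bixel_offsets(self) -> tuple[np.ndarray, np.ndarray]:
        """Isocenter-plane center coordinates (a, b) of the active bixels."""
        nx, ny = self.active.shape
        ax = (np.arange(nx) - 0.5 * (nx - 1)) * self.bixel_width
        by = (np.arange(ny) - 0.5 * (ny - 1)) * self.bixel_width
        aa, bb = np.meshgrid(ax, by, indexing="ij")
        return aa[self.active], bb[self.active]


def aperture_equivalent_square(active: np.ndarray, bixel_width: float) -> float:
    """Equivalent square (4A/P) of the union of active bixels."""
    area = active.sum() * bixel_width**2
    if area == 0:
        raise ValueError("no active bixels")
    padded = np.pad(active, 1)
    edges = (np.abs(np.diff(padded.astype(int), axis=0)).sum()
             + np.abs(np.diff(padded.astype(int), axis=1)).sum())
    perimeter = edges * bixel_width
    return 4.0 * area / perimeter


@dataclass
class BeamGeometry:
    """Precomputed per-beam quantities for the scoring voxels."""

    setup: BeamSetup
    voxel_ids: np.ndarray  # (n,) flat indices into the phantom grid
    iso_x: np.ndarray  # projection of each voxel onto the isocenter plane, cm
    iso_y: np.ndarray
    dist: np.ndarray  # source-to-voxel distance, cm
    rad_depth: np.ndarray  # radiological depth, cm
    eq_square: float


def beam_geometry(model: BeamModel, phantom: VoxelPhantom, setup: BeamSetup,
                  mask: np.ndarray | None = None,
                  heterogeneity: bool = True) -> BeamGeometry:
    """Project scoring voxels into beam coordinates and trace their depths."""
    if mask is None:
        mask = phantom.density > 0
    ids = np.flatnonzero(mask)
    xx, yy, zz = phantom.center_grids()
    pts = np.column_stack([xx.ravel()[ids], yy.ravel()[ids], zz.ravel()[ids]])
    ex, ey, ez = setup.axes()
    src = setup.source
    v = pts - src[None, :]
    t = v @ ez
    t = np.maximum(t, 1e-6)
    dist = np.linalg.norm(v, axis=1)
    iso_x = (v @ ex) * (setup.sad / t)
    iso_y = (v @ ey) * (setup.sad / t)
    if heterogeneity:
        rad = radiological_depth_grid(phantom, src, pts)
    else:
        hom = VoxelPhantom(density=np.ones_like(phantom.density),
                           voxel_size=phantom.voxel_size, origin=phantom.origin)
        rad = radiological_depth_grid(hom, src, pts)
    eq = aperture_equivalent_square(setup.active, setup.bixel_width)
    return BeamGeometry(setup=setup, voxel_ids=ids, iso_x=iso_x, iso_y=iso_y,
                        dist=dist, rad_depth=rad, eq_square=eq)


def beamlet_dose(model: BeamModel, geom: BeamGeometry, bixel: int,
                 cutoff: float = 1e-4) -> tuple[np.ndarray, np.ndarray]:
    """Sparse dose column for one beamlet: (voxel ids, dose per unit weight)."""
    setup = geom.setup
    aa, bb = setup.bixel_offsets()
    if not (0 <= bixel < len(aa)):
        raise IndexError("bixel index outside the active fluence lattice")
    a, b = aa[bixel], bb[bixel]
    hw = 0.5 * setup.bixel_width
    sig = model.kernels.sigmas
    wts = model.kernels.weights
    dx = geom.iso_x[:, None] - a
    dy = geom.iso_y[:, None] - b
    s = np.sqrt(2.0) * sig[None, :]
    fx = 0.5 * (erf((dx + hw) / s) - erf((dx - hw) / s))
    fy = 0.5 * (erf((dy + hw) / s) - erf((dy - hw) / s))
    lateral = (fx * fy) @ wts
    tmr = model.tmr_table.tmr(geom.rad_depth, geom.eq_square)
    of = model.output_factor(geom.eq_square)
    inten = model.intensity(np.hypot(geom.iso_x, geom.iso_y))
    dose = (model.calibration * of * tmr * inten * lateral
            * (setup.sad / geom.dist) ** 2)
    if len(dose) and dose.max() > 0:
        keep = dose >= cutoff * dose.max()
    else:
        keep = np.zeros(len(dose), dtype=bool)
    return geom.voxel_ids[keep], dose[keep]


@dataclass
class InfluenceMatrix:
    """Sparse beamlet-to-voxel dose contribution matrix D (Gy per unit weight)."""

    matrix: sparse.csc_matrix  # (n_voxels_total, n_bixels)
    voxel_shape: tuple[int, int, int]
    bixel_map: list[tuple[int, int]] = field(default_factory=list)  # (beam, bixel)
    cutoff: float = 1e-4

    @property
    def n_bixels(self) -> int:
        return self.matrix.shape[1]

    def dose(self, weights: np.ndarray) -> np.ndarray:
        """Total dose volume d = D w, reshaped to the phantom grid."""
        d = self.matrix @ np.asarray(weights, float)
        return np.asarray(d).reshape(self.voxel_shape)


def influence_matrix(
    model: BeamModel,
    phantom: VoxelPhantom,
    setups: list[BeamSetup],
    mask: np.ndarray | None = None,
    cutoff: float = 1e-4,
    max_entries: float = 2e8,
    heterogeneity: bool = True,
) -> InfluenceMatrix:
    """Stack beamlet dose columns over all beams and active bixels.

    Column ordering is deterministic: beam-major, then row-major over each
    beam's fluence lattice.
    """
    if not setups:
        raise ValueError("at least one beam is required")
    if mask is None:
        mask = phantom.density > 0
    n_cols = sum(int(s.active.sum()) for s in setups)
    if float(mask.sum()) * n_cols > max_entries * 50:
        raise MemoryError(
            "estimated influence-matrix size exceeds the configured cap; "
            "use a coarser dose grid or a smaller scoring mask")
    n_vox = int(np.prod(phantom.shape))
    cols = []
    bixel_map = []
    for ib, setup in enumerate(setups):
        geom = beam_geometry(model, phantom, setup, mask, heterogeneity)
        n_active = int(setup.active.sum())
        for j in range(n_active):
            ids, vals = beamlet_dose(model, geom, j, cutoff)
            cols.append((ids, vals))
            bixel_map.append((ib, j))
    indptr = np.zeros(len(cols) + 1, dtype=np.int64)
    indptr[1:] = np.cumsum([len(ids) for ids, _ in cols])
    indices = np.concatenate([ids for ids, _ in cols]) if cols else np.empty(0, int)
    data = np.concatenate([vals for _, vals in cols]) if cols else np.empty(0)
    mat = sparse.csc_matrix((data, indices, indptr), shape=(n_vox, len(cols)))
    return InfluenceMatrix(matrix=mat, voxel_shape=phantom.shape,
                           bixel_map=bixel_map, cutoff=cutoff)


# ----------------------- open-field water calculations ----------------------

def _cax_aperture_factor(model: BeamModel, width: float) -> float:
    sig = model.kernels.sigmas
    wts = model.kernels.weights
    half = 0.5 * width
    return float((wts * erf(half / (np.sqrt(2.0) * sig)) ** 2).sum())


def openfield_pdd(model: BeamModel, width: float, depths: np.ndarray,
                  ssd: float = 100.0) -> np.ndarray:
    """Central-axis PDD (percent of maximum) of an open square field in water."""
    depths = np.asarray(depths, float)
    tmr = model.tmr_table.tmr(depths, width)
    dose = tmr * (model.sad / (ssd + depths)) ** 2
    return 100.0 * dose / dose.max()


def openfield_cax_dose(model: BeamModel, width: float, depths: np.ndarray,
                       ssd: float = 100.0) -> np.ndarray:
    """Absolute CAX dose (Gy per unit weight) of an open field in water."""
    depths = np.asarray(depths, float)
    tmr = model.tmr_table.tmr(depths, width)
    return (model.calibration * model.output_factor(width)
            * _cax_aperture_factor(model, width) * tmr
            * (model.sad / (ssd + depths)) ** 2)


def openfield_profile(model: BeamModel, width: float, depth: float,
                      x: np.ndarray, ssd: float = 100.0) -> np.ndarray:
    """Lateral open-field profile in water, percent of the CAX value.

    ``x`` are physical off-axis distances in the depth plane.
    """
    x = np.asarray(x, float)
    mag = (ssd + depth) / model.sad
    xi = x / mag
    sig = model.kernels.sigmas
    wts = model.kernels.weights
    half = 0.5 * width
    box = 0.5 * (erf((half - xi[:, None]) / (np.sqrt(2.0) * sig[None, :]))
                 + erf((half + xi[:, None]) / (np.sqrt(2.0) * sig[None, :])))
    aperture = box @ wts
    cax = float((wts * erf(half / (np.sqrt(2.0) * sig))).sum())
    inten = model.intensity(np.abs(xi))
    return 100.0 * aperture * inten / cax
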