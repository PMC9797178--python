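"""Plan and curve evaluation: DVHs, dose indices, integral dose and the
global gamma index.

Conventions:

* Dx% is the dose received by at least x% of a structure, computed as the
  (100 - x) percentile of the voxel doses with linear interpolation between
  order statistics.
* Integral dose is the sum of voxel doses divided by the number of voxels in
  the evaluated volume (mean dose over the body).
* The gamma analysis is global (dose difference normalized to the reference
  maximum) with no low-dose threshold.  For 1-D curves the evaluated
  distribution is treated as a continuous piecewise-linear curve and the
  minimum generalized distance is computed exactly per segment - the limit
  of arbitrarily fine linear up-sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raytrace import radiological_depth

__all__ = ["DVH", "DoseIndexReport", "GammaResult", "compute_dvh",
           "dose_indices", "integral_dose", "average_radiological_depth",
           "gamma_index", "gamma_volume"]


@dataclass
class DVH:
    structure: str
    dose_edges: np.ndarray  # Gy
    volume_fraction: np.ndarray  # cumulative, starts at 1.0

    def validate(self) -> None:
        v = self.volume_fraction
        if abs(v[0] - 1.0) > 1e-12:
            raise ValueError("cumulative DVH must start at 1.0")
        if np.any(np.diff(v) > 1e-12):
            raise ValueError("cumulative DVH must be non-increasing")
        if v[-1] > 1e-12:
            raise ValueError("cumulative DVH must end at 0")

    def volume_at_dose(self, dose: float) -> float:
        return float(np.interp(dose, self.dose_edges, self.volume_fraction))

    def dose_at_volume(self, volume_fraction: float) -> float:
        v = self.volume_fraction
        return float(np.interp(-volume_fraction, -v, self.dose_edges))


def compute_dvh(dose: np.ndarray, mask: np.ndarray, bin_width: float = 0.1,
                structure: str = "structure") -> DVH:
    """Cumulative dose-volume histogram of ``dose`` within ``mask``."""
    d = np.asarray(dose).ravel()[np.asarray(mask).ravel() > 0]
    if d.size == 0:
        raise ValueError("empty structure mask")
    top = max(float(d.max()), bin_width)
    edges = np.arange(0.0, top + 2.0 * bin_width, bin_width)
    frac = (d[None, :] >= edges[:, None]).mean(axis=1)
    frac[0] = 1.0  # every voxel receives at least zero dose
    return DVH(structure=structure, dose_edges=edges, volume_fraction=frac)


@dataclass
class DoseIndexReport:
    per_structure: dict[str, dict[str, float]] = field(default_factory=dict)
    integral_dose: float | None = None  # Gy (mean over evaluated volume)
    average_radiological_depth: float | None = None  # cm
    segment_widths: tuple[float, float] | None = None


def _dx_percent(d: np.ndarray, x: float) -> float:
    """Dose received by at least x% of the structure volume."""
    return float(np.percentile(d, 100.0 - x))


def dose_indices(
    dose: np.ndarray,
    structures: dict[str, np.ndarray],
    voxel_volume: float | None = None,
    hot_volumes_cm3: dict[str, float] | None = None,
) -> DoseIndexReport:
    """D98%, D2%, Dmean, Dmax per structure; optionally D_{v cm^3}.

    D_{v cm^3} (dose to the hottest v cm^3) requires ``voxel_volume``;
    requesting more volume than the structure holds is an error.
    """
    report = DoseIndexReport()
    flat = np.asarray(dose).ravel()
    for name, mask in structures.items():
        d = flat[np.asarray(mask).ravel() > 0]
        if d.size == 0:
            continue
        entry = {
            "D98": _dx_percent(d, 98.0),
            "D2": _dx_percent(d, 2.0),
            "Dmean": float(d.mean()),
            "Dmax": float(d.max()),
        }
        if hot_volumes_cm3 and name in hot_volumes_cm3:
            if voxel_volume is None:
                raise ValueError("voxel_volume required for D_{v cm^3}")
            v = hot_volumes_cm3[name]
            total = d.size * voxel_volume
            if v > total:
                raise ValueError(
                    f"requested hottest {v} cm^3 exceeds the {total:.2f} cm^3 "
                    f"volume of structure {name!r}")
            srt = np.sort(d)[::-1]
            cum = (np.arange(1, d.size + 1)) * voxel_volume
            entry[f"D{v:g}cm3"] = float(np.interp(v, cum, srt))
        report.per_structure[name] = entry
    return report


def integral_dose(dose: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Sum of voxel doses divided by the number of evaluated voxels (Gy)."""
    flat = np.asarray(dose).ravel()
    if mask is not None:
        flat = flat[np.asarray(mask).ravel() > 0]
    return float(flat.mean())


def average_radiological_depth(phantom, setups, ptv_mask: np.ndarray) -> float:
    """Mean over beams of the radiological depth from the patient surface to
    the PTV centroid along each beam's central ray."""
    ids = np.flatnonzero(np.asarray(ptv_mask).ravel())
    if ids.size == 0:
        raise ValueError("empty PTV mask")
    xx, yy, zz = phantom.center_grids()
    centroid = np.array([xx.ravel()[ids].mean(), yy.ravel()[ids].mean(),
                         zz.ravel()[ids].mean()])
    depths = [radiological_depth(phantom, s.source, centroid).radiological_depth
              for s in setups]
    return float(np.mean(depths))


# ------------------------------- gamma index --------------------------------

@dataclass
class GammaResult:
    gamma: np.ndarray
    pass_fraction: float
    criteria: dict = field(default_factory=dict)


def gamma_index(
    reference: tuple[np.ndarray, np.ndarray],
    evaluated: tuple[np.ndarray, np.ndarray],
    dose_percent: float = 2.0,
    dta: float = 0.2,
) -> GammaResult:
    """Global gamma analysis of 1-D dose curves (no low-dose threshold).

    ``reference`` and ``evaluated`` are (positions cm, dose) pairs; the dose
    normalization is ``dose_percent`` of the reference global maximum.  Note
    the analysis is asymmetric: gamma(A -> B) need not equal gamma(B -> A).
    """
    xr, dr = (np.asarray(a, float) for a in reference)
    xe, de = (np.asarray(a, float) for a in evaluated)
    if xe[0] > xr[-1] or xe[-1] < xr[0]:
        raise ValueError("reference and evaluated grids do not overlap")
    scale = dose_percent / 100.0 * float(np.max(dr))
    # normalized coordinates
    ur, vr = xr / dta, dr / scale
    ue, ve = xe / dta, de / scale
    # distance from each reference point to each evaluated segment
    p = np.stack([ur, vr], axis=1)  # (n, 2)
    a = np.stack([ue[:-1], ve[:-1]], axis=1)  # (m, 2)
    b = np.stack([ue[1:], ve[1:]], axis=1)
    ab = b - a
    denom = np.maximum((ab**2).sum(axis=1), 1e-300)
    ap = p[:, None, :] - a[None, :, :]
    t = np.clip((ap * ab[None, :, :]).sum(axis=2) / denom[None, :], 0.0, 1.0)
    closest = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    dist = np.sqrt(((p[:, None, :] - closest) ** 2).sum(axis=2))
    gamma = dist.min(axis=1)
    return GammaResult(
        gamma=gamma,
        pass_fraction=float(np.mean(gamma <= 1.0)),
        criteria={"dose_percent": dose_percent, "dta_cm": dta,
                  "normalization": "global-max", "threshold": None},
    )


def gamma_volume(
    reference: np.ndarray,
    evaluated: np.ndarray,
    voxel_size,
    dose_percent: float = 2.0,
    dta: float = 0.2,
    search_radius_factor: float = 3.0,
    subdivision: int = 5,
) -> GammaResult:
    """Global gamma analysis of two dose volumes on the same grid.

    Exhaustive search over displacement offsets on a lattice of spacing
    ``dta / subdivision`` within ``search_radius_factor * dta``, evaluating
    the displaced distribution by trilinear interpolation.  Intended for
    small grids; cost grows with the cube of the subdivision.
    """
    from scipy.ndimage import map_coordinates

    ref = np.asarray(reference, float)
    ev = np.asarray(evaluated, float)
    if ref.shape != ev.shape:
        raise ValueError("volumes must share one grid")
    vox = np.asarray(voxel_size, float)
    scale = dose_percent / 100.0 * float(ref.max())
    radius = search_radius_factor * dta
    step = dta / subdivision
    offsets = [np.arange(-radius, radius + 0.5 * step, step) for _ in range(3)]
    base = np.indices(ref.shape).reshape(3, -1).astype(float)
    gamma2 = np.full(ref.size, np.inf)
    for ox in offsets[0]:
        for oy in offsets[1]:
            for oz in offsets[2]:
                r2 = (ox**2 + oy**2 + oz**2) / dta**2
                if r2 > search_radius_factor**2 or r2 >= gamma2.max():
                    continue
                coords = base + (np.array([ox, oy, oz]) / vox)[:, None]
                shifted = map_coordinates(ev, coords, order=1, mode="nearest")
                dd2 = (shifted - ref.ravel()) ** 2 / scale**2
                gamma2 = np.minimum(gamma2, dd2 + r2)
    gamma = np.sqrt(gamma2)
    return GammaResult(
        gamma=gamma.reshape(ref.shape),
        pass_fraction=float(np.mean(gamma <= 1.0)),
        criteria={"dose_percent": dose_percent, "dta_cm": dta,
                  "normalization": "global-max", "threshold": None,
                  "subdivision": subdivision},
    )
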