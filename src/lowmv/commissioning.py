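"""Beam-model commissioning from a scan set.

Pipeline: extract d_max per field, convert PDD -> TMR with peak scatter
factor set to unity, seed the fluence ("intensity") profile from the diagonal
scan, tune it against computed profiles, and fit decomposed lateral pencil
beam kernels (a small sum of Gaussians) to the measured profiles.  The result
is a machine database (BeamModel) sufficient for pencil-beam dose
calculation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy.optimize import least_squares
from scipy.special import erf

from .scans import SAD, BeamScanSet

__all__ = [
    "TMRTable",
    "IntensityProfile",
    "KernelSet",
    "BeamModel",
    "KernelFitError",
    "extract_dmax",
    "extract_dd10",
    "pdd_to_tmr",
    "equivalent_square",
    "tune_intensity_profile",
    "fit_kernels",
    "build_beam_model",
    "load_beam_model",
]


class KernelFitError(RuntimeError):
    pass


def extract_dmax(depths: np.ndarray, values: np.ndarray) -> float:
    """Depth of maximum via parabolic interpolation through the three highest
    samples; ties resolve toward the smaller depth."""
    i = int(np.argmax(values))
    if i == 0 or i == len(values) - 1:
        return float(depths[i])
    if values[i + 1] == values[i]:  # exact tie: smaller depth wins
        return float(depths[i])
    d0, d1, d2 = depths[i - 1], depths[i], depths[i + 1]
    y0, y1, y2 = values[i - 1], values[i], values[i + 1]
    denom = (y0 - 2.0 * y1 + y2)
    if denom >= 0:  # flat or degenerate
        return float(d1)
    # uniform-grid parabola vertex
    h = 0.5 * (d2 - d0)
    shift = 0.5 * (y0 - y2) / denom * h
    return float(d1 + np.clip(shift, d0 - d1, d2 - d1))


def extract_dd10(depths: np.ndarray, values: np.ndarray) -> float:
    """PDD value at 10 cm depth (percent of maximum), linear interpolation."""
    return float(np.interp(10.0, depths, 100.0 * values / np.max(values)))


def pdd_to_tmr(pdd_curve: tuple[np.ndarray, np.ndarray], ssd: float,
               d_max: float) -> tuple[np.ndarray, np.ndarray]:
    """Convert a PDD (percent of maximum) to TMR with PSF == 1:

        TMR(d) = (PDD(d)/100) * ((ssd + d) / (ssd + d_max))^2
    """
    depths, pdd = pdd_curve
    depths = np.asarray(depths, float)
    pdd = np.asarray(pdd, float)
    if ssd <= 0:
        raise ValueError("ssd must be positive")
    if not (depths[0] - 1e-9 <= d_max <= depths[-1] + 1e-9):
        raise ValueError(f"d_max={d_max} outside the PDD depth grid")
    tmr = (pdd / 100.0) * ((ssd + depths) / (ssd + d_max)) ** 2
    return depths, tmr


def equivalent_square(width_x: float, width_y: float) -> float:
    """Equivalent square of a rectangular aperture, 4*Area/Perimeter."""
    return 2.0 * width_x * width_y / (width_x + width_y)


@dataclass
class TMRTable:
    depths: np.ndarray  # cm
    field_sizes: np.ndarray  # equivalent-square side lengths, cm
    values: np.ndarray  # (n_depth, n_field)
    d_max: dict[float, float] = field(default_factory=dict)  # per field

    def validate(self) -> None:
        for j, w in enumerate(self.field_sizes):
            col = self.values[:, j]
            dm = self.d_max.get(float(w))
            if dm is not None:
                tmr_dm = np.interp(dm, self.depths, col)
                if abs(tmr_dm - 1.0) > 1e-6:
                    raise ValueError(f"TMR at d_max != 1 for field {w} ({tmr_dm})")
            if np.any(col < 0):
                raise ValueError("negative TMR")

    def tmr(self, depth, field_size) -> np.ndarray:
        """Bilinear lookup: linear in depth, linear in field side length.

        Depths outside the grid clamp to the end values; field sizes are
        linearly extrapolated (small fields) down to 2 cm, then clamped.
        """
        depth = np.asarray(depth, dtype=float)
        fs = float(np.clip(field_size, 2.0, None))
        f = self.field_sizes
        if fs <= f[0]:
            j0, j1 = 0, 1
        elif fs >= f[-1]:
            j0, j1 = len(f) - 2, len(f) - 1
        else:
            j1 = int(np.searchsorted(f, fs))
            j0 = j1 - 1
        t = (fs - f[j0]) / (f[j1] - f[j0])
        c0 = np.interp(depth, self.depths, self.values[:, j0])
        c1 = np.interp(depth, self.depths, self.values[:, j1])
        return (1.0 - t) * c0 + t * c1


@dataclass
class IntensityProfile:
    radius: np.ndarray  # off-axis radius at isocenter, cm
    value: np.ndarray  # relative fluence, 1.0 on axis

    def validate(self) -> None:
        i0 = int(np.argmin(np.abs(self.radius)))
        if abs(self.value[i0] - 1.0) > 1e-9:
            raise ValueError("intensity profile must be 1.0 on axis")
        if np.any(self.value < 0):
            raise ValueError("intensity profile must be nonnegative")

    def __call__(self, r) -> np.ndarray:
        return np.interp(np.abs(r), self.radius, self.value)


@dataclass
class KernelSet:
    weights: np.ndarray
    sigmas: np.ndarray  # cm, at the isocenter plane, strictly increasing

    def validate(self) -> None:
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("kernel weights must sum to 1")
        if np.any(self.sigmas <= 0) or np.any(np.diff(self.sigmas) <= 0):
            raise ValueError("kernel sigmas must be positive and strictly increasing")

    @property
    def n_components(self) -> int:
        return len(self.weights)


@dataclass
class BeamModel:
    """Commissioned machine database for one beam quality."""

    beam_label: str
    tmr_table: TMRTable
    output_factors: dict[float, float]
    intensity: IntensityProfile
    kernels: KernelSet
    sad: float = SAD
    ssd_ref: float = 100.0
    reference_field: float = 10.0
    calibration: float = 1.0  # Gy per unit bixel weight at d_max, reference field
    residual_report: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        self.tmr_table.validate()
        self.kernels.validate()
        if abs(self.output_factors.get(self.reference_field, 1.0) - 1.0) > 1e-9:
            raise ValueError("output factor at the reference field must be 1")

    def output_factor(self, field_size: float) -> float:
        f = np.array(sorted(self.output_factors))
        v = np.array([self.output_factors[k] for k in f])
        fs = np.clip(field_size, f[0], f[-1])
        return float(np.interp(fs, f, v))

    # -------------------------- persistence ---------------------------------

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with h5py.File(path, "w") as h5:
            h5.attrs["format"] = "lowmv-beam-model/1"
            h5.attrs["beam_label"] = self.beam_label
            h5.attrs["sad"] = self.sad
            h5.attrs["ssd_ref"] = self.ssd_ref
            h5.attrs["reference_field"] = self.reference_field
            h5.attrs["calibration"] = self.calibration
            h5.attrs["residual_report"] = json.dumps(self.residual_report)
            h5.attrs["provenance"] = json.dumps(self.provenance)
            h5.create_dataset("tmr/depths", data=self.tmr_table.depths)
            h5.create_dataset("tmr/fields", data=self.tmr_table.field_sizes)
            h5.create_dataset("tmr/values", data=self.tmr_table.values)
            dmx = np.array(sorted(self.tmr_table.d_max.items()))
            h5.create_dataset("tmr/dmax", data=dmx)
            ofs = np.array(sorted(self.output_factors.items()))
            h5.create_dataset("output_factors", data=ofs)
            h5.create_dataset("intensity/radius", data=self.intensity.radius)
            h5.create_dataset("intensity/value", data=self.intensity.value)
            h5.create_dataset("kernels/weights", data=self.kernels.weights)
            h5.create_dataset("kernels/sigmas", data=self.kernels.sigmas)
        return path


def load_beam_model(path: str | Path) -> BeamModel:
    with h5py.File(path, "r") as h5:
        dmx = h5["tmr/dmax"][()]
        model = BeamModel(
            beam_label=h5.attrs["beam_label"],
            tmr_table=TMRTable(
                depths=h5["tmr/depths"][()],
                field_sizes=h5["tmr/fields"][()],
                values=h5["tmr/values"][()],
                d_max={float(a): float(b) for a, b in dmx},
            ),
            output_factors={float(a): float(b) for a, b in h5["output_factors"][()]},
            intensity=IntensityProfile(radius=h5["intensity/radius"][()],
                                       value=h5["intensity/value"][()]),
            kernels=KernelSet(weights=h5["kernels/weights"][()],
                              sigmas=h5["kernels/sigmas"][()]),
            sad=float(h5.attrs["sad"]),
            ssd_ref=float(h5.attrs["ssd_ref"]),
            reference_field=float(h5.attrs["reference_field"]),
            calibration=float(h5.attrs["calibration"]),
            residual_report=json.loads(h5.attrs["residual_report"]),
            provenance=json.loads(h5.attrs["provenance"]),
        )
    return model


# ------------------------- intensity-profile tuning -------------------------

def _default_profile_engine(model: BeamModel, width: float, depth: float,
                            x: np.ndarray) -> np.ndarray:
    from . import dose  # local import to avoid a cycle

    return dose.openfield_profile(model, width, depth, x)


def tune_intensity_profile(
    scan: BeamScanSet,
    model: BeamModel,
    engine=None,
    tol: float = 1e-3,
    max_iter: int = 50,
    n_control: int = 10,
) -> tuple[IntensityProfile, dict]:
    """Iteratively rescale intensity control points to match measured profiles.

    Coordinate-wise multiplicative updates driven by the ratio of measured to
    computed profile values at matched isocenter radii.  Returns the tuned
    profile and a report with the deviation trace and a convergence flag; on
    non-convergence the best profile found so far is returned, flagged.
    """
    engine = engine or _default_profile_engine
    r_max = float(np.max(np.abs(scan.diagonal_profile[0])))
    control = np.linspace(0.0, r_max, n_control)
    values = model.intensity(control)
    values = values / values[0]

    def in_field_dev(profile: IntensityProfile) -> float:
        trial = BeamModel(model.beam_label, model.tmr_table, model.output_factors,
                          profile, model.kernels, model.sad, model.ssd_ref,
                          model.reference_field, model.calibration)
        dev = 0.0
        for w, per_depth in scan.profiles.items():
            for dep, (x, meas) in per_depth.items():
                comp = engine(trial, w, dep, x)
                sel = meas >= 80.0
                if sel.any():
                    dev = max(dev, float(np.max(np.abs(comp[sel] - meas[sel]))))
        return dev

    def ratios(profile: IntensityProfile) -> np.ndarray:
        trial = BeamModel(model.beam_label, model.tmr_table, model.output_factors,
                          profile, model.kernels, model.sad, model.ssd_ref,
                          model.reference_field, model.calibration)
        num = np.zeros_like(control)
        cnt = np.zeros_like(control)
        for w, per_depth in scan.profiles.items():
            for dep, (x, meas) in per_depth.items():
                mag = (scan.ssd + dep) / model.sad
                xk = control * mag
                inside = xk <= np.max(x)
                m_k = np.interp(xk, x, np.where(x >= 0, meas, np.nan),
                                left=np.nan, right=np.nan)
                xs = x[x >= 0]
                m_k = np.interp(xk, xs, meas[x >= 0])
                c_k = np.interp(xk, xs, engine(trial, w, dep, x)[x >= 0])
                ok = inside & (m_k >= 50.0) & (c_k > 0)
                num[ok] += m_k[ok] / c_k[ok]
                cnt[ok] += 1
        r = np.where(cnt > 0, num / np.maximum(cnt, 1), 1.0)
        return np.clip(r, 0.5, 2.0)

    trace = []
    best_vals = values.copy()
    dev_prev = in_field_dev(IntensityProfile(control, values))
    best_dev = dev_prev
    trace.append(dev_prev)
    converged = False
    for _ in range(max_iter):
        values = values * ratios(IntensityProfile(control, values))
        values = values / values[0]
        dev = in_field_dev(IntensityProfile(control, values))
        trace.append(dev)
        if dev < best_dev:
            best_dev, best_vals = dev, values.copy()
        if dev_prev - dev < tol:  # improvement stalled (or reversed)
            converged = True
            break
        dev_prev = dev
    report = {"deviation_trace": trace, "converged": bool(converged),
              "max_in_field_deviation_percent": float(best_dev)}
    return IntensityProfile(control, best_vals), report


# ------------------------------ kernel fitting ------------------------------

def _profile_model(x: np.ndarray, width: float, depth: float, ssd: float,
                   sad: float, weights: np.ndarray, sigmas: np.ndarray,
                   intensity: IntensityProfile) -> np.ndarray:
    mag = (ssd + depth) / sad
    half = 0.5 * width * mag
    sig = sigmas * mag
    box = 0.5 * (erf((half - x[:, None]) / (np.sqrt(2) * sig[None, :]))
                 + erf((half + x[:, None]) / (np.sqrt(2) * sig[None, :])))
    aperture = box @ weights
    cax = (erf(half / (np.sqrt(2) * sig)) * weights).sum()
    fl = intensity(np.abs(x) / mag)
    return 100.0 * aperture * fl / cax


def fit_kernels(
    scan: BeamScanSet,
    tmr: TMRTable,
    intensity: IntensityProfile,
    n_components: int = 3,
    sigma_init: np.ndarray | None = None,
) -> tuple[KernelSet, dict]:
    """Least-squares fit of decomposed lateral kernel weights and widths.

    Fits ``n_components`` Gaussians (weights summing to 1, widths strictly
    increasing by construction) to all measured profiles; output factors are
    carried as targets and their residuals reported.
    """
    if len(scan.profiles) < 3:
        raise ValueError("need profiles for at least 3 field sizes")
    datasets = []
    for w, per_depth in scan.profiles.items():
        for dep, (x, meas) in per_depth.items():
            datasets.append((w, dep, x, meas))
    if sigma_init is None:
        sigma_init = 0.35 * np.geomspace(1.0, 8.0, n_components)

    def unpack(theta):
        loginc = theta[:n_components]
        sig = np.cumsum(np.exp(loginc))
        if n_components > 1:
            wts = np.exp(np.append(theta[n_components:], 0.0))
            wts = wts / wts.sum()
        else:
            wts = np.array([1.0])
        return wts, sig

    def resid(theta):
        wts, sig = unpack(theta)
        out = []
        for w, dep, x, meas in datasets:
            comp = _profile_model(x, w, dep, scan.ssd, SAD, wts, sig, intensity)
            out.append((comp - meas) / 100.0)
        return np.concatenate(out)

    inc0 = np.diff(np.concatenate([[0.0], sigma_init]))
    theta0 = np.concatenate([np.log(np.clip(inc0, 1e-3, None)),
                             np.linspace(1.5, 0.5, n_components - 1)])
    sol = least_squares(resid, theta0, xtol=1e-12, ftol=1e-12, max_nfev=400)
    if not np.all(np.isfinite(sol.x)):
        raise KernelFitError("kernel fit diverged to non-finite parameters")
    weights, sigmas = unpack(sol.x)
    tiny = weights < 1e-8
    if tiny.any():
        raise KernelFitError(
            f"degenerate kernel fit: component(s) {np.where(tiny)[0].tolist()} "
            "collapsed to zero weight; reduce n_components")
    kernels = KernelSet(weights=weights, sigmas=sigmas)
    kernels.validate()

    # residual report: profiles and output factors
    prof_resid = {}
    for w, dep, x, meas in datasets:
        comp = _profile_model(x, w, dep, scan.ssd, SAD, weights, sigmas, intensity)
        prof_resid[f"{w:g}cm@{dep:g}cm"] = float(np.max(np.abs(comp - meas)))
    ref = scan.ssd  # reference depth factor for OF residuals: use 10 cm depth
    psi = {}
    for w in scan.field_widths:
        mag = (ref + 10.0) / SAD
        half = 0.5 * w * mag
        psi[w] = float((weights * erf(half / (np.sqrt(2) * sigmas * mag)) ** 2).sum())
    of_resid = {f"{w:g}": float(scan.output_factors[w] * psi[w] / psi[10.0]
                                - scan.output_factors[w])
                for w in scan.field_widths if 10.0 in psi}
    report = {"profile_max_abs_percent": prof_resid, "of_residual": of_resid,
              "cost": float(sol.cost)}
    return kernels, report


# ------------------------------ composition ---------------------------------

def build_beam_model(scan: BeamScanSet, n_components: int = 3,
                     tune: bool = True, save_path: str | Path | None = None
                     ) -> BeamModel:
    """Commission a BeamModel from a BeamScanSet.

    Composes d_max extraction, PDD->TMR conversion (PSF = 1), intensity
    profile seeding + tuning, and lateral-kernel fitting; optionally persists
    the model as an HDF5 beam database with provenance metadata.
    """
    scan.validate()
    fields = np.array(sorted(scan.pdd_curves))
    depths = scan.pdd_curves[fields[0]][0]
    values = np.zeros((len(depths), len(fields)))
    dmax_by_field: dict[float, float] = {}
    for j, w in enumerate(fields):
        d, p = scan.pdd_curves[w]
        dm = extract_dmax(d, p)
        dmax_by_field[float(w)] = dm
        _, tmr = pdd_to_tmr((d, p), scan.ssd, dm)
        col = np.interp(depths, d, tmr)
        # renormalize so the tabulated column is exactly 1 at the interpolated d_max
        values[:, j] = col / np.interp(dm, depths, col)
    tmr_table = TMRTable(depths=depths, field_sizes=fields.astype(float),
                         values=values, d_max=dmax_by_field)

    r, v = scan.diagonal_profile
    pos = r >= 0
    intensity = IntensityProfile(radius=r[pos], value=v[pos] / v[pos][0])

    # quick single-Gaussian penumbra estimate to seed the kernels
    x, p = scan.profiles[10.0][sorted(scan.profiles[10.0])[0]]
    xs = x[x >= 0]
    ps = p[x >= 0]
    x80 = np.interp(-80.0, -ps, xs)
    x20 = np.interp(-20.0, -ps, xs)
    sig0 = max((x20 - x80) / 1.6832, 0.05)
    kernels = KernelSet(weights=np.array([1.0]), sigmas=np.array([sig0]))

    model = BeamModel(
        beam_label=scan.beam_label,
        tmr_table=tmr_table,
        output_factors=dict(scan.output_factors),
        intensity=intensity,
        kernels=kernels,
        provenance={"source": "build_beam_model", "ssd": scan.ssd,
                    "fields": fields.tolist()},
    )
    reports: dict = {}
    model.kernels, _ = fit_kernels(scan, tmr_table, model.intensity,
                                   n_components=n_components)
    if tune:
        model.intensity, reports["intensity_tuning"] = tune_intensity_profile(scan, model)
    model.kernels, reports["kernel_fit"] = fit_kernels(
        scan, tmr_table, model.intensity, n_components=n_components)
    model.residual_report = reports
    model.validate()
    if save_path is not None:
        model.save(save_path)
    return model
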