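"""Synthetic beam-scan data emulating water-tank commissioning measurements.

A scan set holds, per square field size, a central-axis percentage depth-dose
curve (PDD), lateral dose profiles at several depths, an output factor, and -
for the largest field - a diagonal fluence ("intensity") profile, i.e. the
data a physicist would export from a water-phantom scanning system.

Depth dose follows a two-exponential model

    pdd(d)  ~  [exp(-mu d) - c exp(-beta d)] * S(d, W)

with (mu, beta, c) solved so that the 10x10 cm^2 curve attains its maximum at
the requested d_max, the requested %dd10 at 10 cm, and the requested surface
dose at d = 0.  S(d, W) = 1 + a d W/(W + W0) is a scatter-volume factor giving
the mild field-size dependence of depth dose.  Lateral profiles combine an
error-function penumbra, a broad scatter tail and a centre-peaked
flattening-filter-free (FFF) fluence factor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import erf

__all__ = [
    "BeamQualitySpec",
    "BeamScanSet",
    "ParameterError",
    "generate_beam_scan_set",
    "beam_quality_2p5mv",
    "beam_quality_6mv",
    "load_beam_scan_set",
    "fff_intensity",
]

SAD = 100.0
DEFAULT_FIELD_WIDTHS = (4.0, 6.0, 8.0, 10.0, 20.0, 40.0)
PROFILE_DEPTH_LABELS = ("dmax", 5.0, 10.0, 20.0)

# Depth dose is modeled as a two-exponential core times a scatter-volume
# factor:
#   pdd(d, W) ~ [exp(-mu d) - c exp(-beta d)] * (1 + B * b(d)) * r(d, W)
# with a reference-field (10 cm) scatter factor
#   b(d) = 1 - exp(-d / SPR_BROAD_D0),  B = SPR_BROAD
# and a field-size modulation taken relative to the reference field,
#   r(d, W) = (1 + A(W) s(d)) / (1 + A(10) s(d)),
#   s(d) = 1 - exp(-(d / SPR_D0)^SPR_P),
#   A(W) = SPR_OFF + SPR_SLP * W/(W + SPR_W0).
# The reference-field shape and the field-size ratio structure were each
# calibrated once against the package's own Monte Carlo water depth-dose
# curves (fields 2-40 cm); see docs/methods.md.
SPR_BROAD = 0.258
SPR_BROAD_D0 = 4.5
SPR_OFF = -0.1511
SPR_SLP = 5.7593
SPR_W0 = 62.40
SPR_D0 = 15.03
SPR_P = 1.14

# Broad scatter-tail fraction and width (at isocenter plane) of the profiles.
TAIL_FRACTION = 0.04
TAIL_SIGMA = 2.5
# FFF intensity fall-off is referenced to a 20 cm off-axis radius.
FFF_REFERENCE_RADIUS = 20.0
# 80-20 penumbra width of an erf edge is 2*z_{0.8} = 1.683 sigma.
_PENUMBRA_TO_SIGMA = 1.0 / 1.6832


class ParameterError(ValueError):
    """Raised when a beam-quality specification admits no depth-dose model."""


@dataclass(frozen=True)
class BeamQualitySpec:
    """Printable beam-quality indices that pin down a synthetic beam."""

    d_max: float  # cm
    dd10: float  # percent of maximum at 10 cm depth
    surface_dose: float = 60.0  # percent of maximum at d = 0
    profile_horn_fraction: float = 0.3  # fractional fluence drop at 20 cm off axis
    penumbra_width_80_20: float = 0.6  # cm at isocenter plane

    def __post_init__(self) -> None:
        if not (0.0 < self.d_max < 5.0):
            raise ParameterError(f"d_max must lie in (0, 5) cm, got {self.d_max}")
        if not (0.0 < self.dd10 < 100.0):
            raise ParameterError(f"%dd10 must lie in (0, 100), got {self.dd10}")
        if not (0.0 <= self.surface_dose < 100.0):
            raise ParameterError(f"surface dose must lie in [0, 100), got {self.surface_dose}")
        if not (0.0 <= self.profile_horn_fraction < 1.0):
            raise ParameterError("profile horn fraction must lie in [0, 1)")
        if self.penumbra_width_80_20 <= 0:
            raise ParameterError("penumbra width must be positive")


def beam_quality_2p5mv() -> BeamQualitySpec:
    """2.5 MV FFF imaging-class beam: shallow d_max, fast fall-off."""
    return BeamQualitySpec(d_max=0.6, dd10=55.0, surface_dose=70.0,
                           profile_horn_fraction=0.45, penumbra_width_80_20=0.6)


def beam_quality_6mv() -> BeamQualitySpec:
    """Conventional flattened 6 MV treatment beam."""
    return BeamQualitySpec(d_max=1.5, dd10=70.0, surface_dose=55.0,
                           profile_horn_fraction=0.05, penumbra_width_80_20=0.7)


def fff_intensity(radius_iso: np.ndarray, horn_fraction: float) -> np.ndarray:
    """Centre-peaked FFF fluence factor, 1 on axis, monotone decreasing.

    ``horn_fraction`` is the fractional drop at 20 cm off-axis radius.
    """
    r = np.asarray(radius_iso, dtype=float)
    if horn_fraction <= 0.0:
        return np.ones_like(r)
    return np.exp(np.log1p(-horn_fraction) * (r / FFF_REFERENCE_RADIUS) ** 2)


def _scatter_amp(width: float) -> float:
    return SPR_OFF + SPR_SLP * width / (width + SPR_W0)


def _scatter_shape(depth: np.ndarray) -> np.ndarray:
    d = np.asarray(depth, dtype=float)
    return 1.0 - np.exp(-((d / SPR_D0) ** SPR_P))


def _depth_dose(depth: np.ndarray, width: float, mu: float, beta: float,
                c: float) -> np.ndarray:
    d = np.asarray(depth, dtype=float)
    core = np.exp(-mu * d) - c * np.exp(-beta * d)
    broad = 1.0 + SPR_BROAD * (1.0 - np.exp(-d / SPR_BROAD_D0))
    s = _scatter_shape(d)
    ratio = (1.0 + _scatter_amp(width) * s) / (1.0 + _scatter_amp(10.0) * s)
    return core * broad * ratio


def solve_depth_dose(spec: BeamQualitySpec, reference_width: float = 10.0
                     ) -> tuple[float, float, float]:
    """Solve (mu, beta, c) of the two-exponential model for one beam quality."""

    q = spec.dd10 / 100.0
    s0 = spec.surface_dose / 100.0
    dm = spec.d_max
    w = reference_width

    def resid(x):
        mu, beta, c = np.exp(x[0]), np.exp(x[1]), 1.0 / (1.0 + np.exp(-x[2]))

        def g(d):
            return float(_depth_dose(np.array([d]), w, mu, beta, c)[0])

        h = 1e-5
        peak = g(dm)
        r1 = (g(dm + h) - g(dm - h)) / (2.0 * h) / peak  # stationarity at d_max
        r2 = g(10.0) / peak - q
        r3 = (1.0 - c) / peak - s0
        return [r1, r2, r3]

    mu0 = max(np.log(1.0 / max(q, 1e-3)) / max(10.0 - dm, 1.0), 1e-3)
    x0 = [np.log(mu0), np.log(4.0 / dm), 0.0]
    sol = least_squares(resid, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-6:
        raise ParameterError(
            "no two-exponential depth dose satisfies d_max="
            f"{dm} cm, %dd10={spec.dd10}, surface={spec.surface_dose}%: the "
            "fall-off and buildup constraints are mutually inconsistent")
    mu, beta, c = np.exp(sol.x[0]), np.exp(sol.x[1]), 1.0 / (1.0 + np.exp(-sol.x[2]))
    if beta <= mu:
        raise ParameterError(
            f"degenerate depth-dose solution (beta={beta:.4f} <= mu={mu:.4f}); "
            "requested %dd10 is too high for the requested d_max")
    return float(mu), float(beta), float(c)


@dataclass
class BeamScanSet:
    """Measured-style commissioning dataset for one beam quality."""

    beam_label: str
    ssd: float
    field_widths: list[float]
    # per field width: (depth grid cm, percent of maximum)
    pdd_curves: dict[float, tuple[np.ndarray, np.ndarray]]
    # per field width, per depth cm: (off-axis distance cm, percent of CAX max)
    profiles: dict[float, dict[float, tuple[np.ndarray, np.ndarray]]]
    # (off-axis distance at isocenter cm, relative fluence)
    diagonal_profile: tuple[np.ndarray, np.ndarray]
    # per field width, normalized to 1 at the 10 cm field
    output_factors: dict[float, float]
    quality: BeamQualitySpec | None = None

    def validate(self) -> None:
        for w, (d, p) in self.pdd_curves.items():
            if not np.all(np.diff(d) > 0):
                raise ValueError(f"PDD depth grid for field {w} is not strictly increasing")
            if np.count_nonzero(p == 100.0) != 1:
                raise ValueError(f"PDD for field {w} must peak at exactly one 100% sample")
            if np.any(p < 0):
                raise ValueError("negative PDD values")
        for w, per_depth in self.profiles.items():
            for dep, (x, p) in per_depth.items():
                if not np.all(np.diff(x) > 0):
                    raise ValueError("profile off-axis grid is not strictly increasing")
                if np.any(p < 0):
                    raise ValueError("negative profile values")
        if 10.0 in self.output_factors and abs(self.output_factors[10.0] - 1.0) > 1e-12:
            raise ValueError("output factor at the 10 cm field must be 1.0")

    # ---------------- serialization (CSV directory + JSON manifest) ---------

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        files: dict[str, str] = {}
        for w, (d, p) in self.pdd_curves.items():
            name = f"pdd_{w:g}cm.csv"
            pd.DataFrame({"depth_cm": d, "percent": p}).to_csv(directory / name, index=False)
            files[f"pdd/{w:g}"] = name
        for w, per_depth in self.profiles.items():
            for dep, (x, p) in per_depth.items():
                name = f"profile_{w:g}cm_d{dep:g}cm.csv"
                pd.DataFrame({"offaxis_cm": x, "percent": p}).to_csv(directory / name, index=False)
                files[f"profile/{w:g}/{dep:g}"] = name
        r, v = self.diagonal_profile
        pd.DataFrame({"offaxis_cm": r, "relative": v}).to_csv(directory / "diagonal.csv", index=False)
        files["diagonal"] = "diagonal.csv"
        pd.DataFrame({
            "field_cm": list(self.output_factors),
            "output_factor": list(self.output_factors.values()),
        }).to_csv(directory / "output_factors.csv", index=False)
        files["output_factors"] = "output_factors.csv"
        manifest = {
            "format": "lowmv-beam-scan-set/1",
            "beam_label": self.beam_label,
            "ssd_cm": self.ssd,
            "field_widths_cm": list(self.field_widths),
            "files": files,
            "quality": None if self.quality is None else vars(self.quality),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return directory


def load_beam_scan_set(directory: str | Path) -> BeamScanSet:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    pdd: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    profiles: dict[float, dict[float, tuple[np.ndarray, np.ndarray]]] = {}
    for key, name in manifest["files"].items():
        parts = key.split("/")
        df = pd.read_csv(directory / name)
        if parts[0] == "pdd":
            pdd[float(parts[1])] = (df["depth_cm"].to_numpy(), df["percent"].to_numpy())
        elif parts[0] == "profile":
            profiles.setdefault(float(parts[1]), {})[float(parts[2])] = (
                df["offaxis_cm"].to_numpy(), df["percent"].to_numpy())
    diag = pd.read_csv(directory / manifest["files"]["diagonal"])
    ofs = pd.read_csv(directory / manifest["files"]["output_factors"])
    quality = manifest.get("quality")
    return BeamScanSet(
        beam_label=manifest["beam_label"],
        ssd=manifest["ssd_cm"],
        field_widths=[float(w) for w in manifest["field_widths_cm"]],
        pdd_curves=pdd,
        profiles=profiles,
        diagonal_profile=(diag["offaxis_cm"].to_numpy(), diag["relative"].to_numpy()),
        output_factors=dict(zip(ofs["field_cm"], ofs["output_factor"])),
        quality=None if quality is None else BeamQualitySpec(**quality),
    )


def _profile_percent(x: np.ndarray, width: float, depth: float, ssd: float,
                     spec: BeamQualitySpec) -> np.ndarray:
    """Lateral dose profile (percent of CAX value) at one depth."""
    mag = (ssd + depth) / SAD
    half = 0.5 * width * mag
    sig_p = spec.penumbra_width_80_20 * _PENUMBRA_TO_SIGMA * mag
    sig_t = TAIL_SIGMA * mag

    def box(sig):
        return 0.5 * (erf((half - x) / (np.sqrt(2) * sig)) + erf((half + x) / (np.sqrt(2) * sig)))

    aperture = (1.0 - TAIL_FRACTION) * box(sig_p) + TAIL_FRACTION * box(sig_t)
    fluence = fff_intensity(np.abs(x) / mag, spec.profile_horn_fraction)
    cax = (1.0 - TAIL_FRACTION) * erf(half / (np.sqrt(2) * sig_p)) \
        + TAIL_FRACTION * erf(half / (np.sqrt(2) * sig_t))
    return 100.0 * aperture * fluence / cax


def output_factor(width: float) -> float:
    """Head+phantom scatter output factor, normalized to the 10 cm field."""
    return float(1.0 + 0.05 * np.log(width / 10.0))


def generate_beam_scan_set(
    spec: BeamQualitySpec,
    field_widths: tuple[float, ...] = DEFAULT_FIELD_WIDTHS,
    seed: int = 0,
    *,
    beam_label: str = "beam",
    ssd: float = 100.0,
    depth_step: float = 0.1,
    max_depth: float = 30.0,
    noise_percent: float = 0.0,
) -> BeamScanSet:
    """Generate a full commissioning scan set for one beam quality.

    ``noise_percent`` adds seeded Gaussian noise (percent of local value) to
    every curve; the default 0 yields byte-identical output for a fixed seed.
    """
    widths = sorted(float(w) for w in field_widths)
    if not widths or max(widths) < 10.0:
        raise ParameterError("at least one field width >= 10 cm is required")
    mu, beta, c = solve_depth_dose(spec)
    rng = np.random.default_rng(seed)

    depths = np.round(np.arange(0.0, max_depth + 0.5 * depth_step, depth_step), 6)
    pdd_curves: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    profiles: dict[float, dict[float, tuple[np.ndarray, np.ndarray]]] = {}
    for w in widths:
        raw = _depth_dose(depths, w, mu, beta, c)
        if noise_percent > 0.0:
            raw = raw * (1.0 + 0.01 * noise_percent * rng.standard_normal(raw.shape))
        pdd = (raw / raw.max()) * 100.0
        pdd_curves[w] = (depths, pdd)

        per_depth: dict[float, tuple[np.ndarray, np.ndarray]] = {}
        d_peak = depths[int(np.argmax(pdd))]
        for dep in (d_peak, 5.0, 10.0, 20.0):
            mag = (ssd + dep) / SAD
            n_half = int(np.ceil((0.75 * w * mag + 4.0) / 0.1))
            x = np.arange(-n_half, n_half + 1) * 0.1
            p = _profile_percent(x, w, dep, ssd, spec)
            if noise_percent > 0.0:
                p = p * (1.0 + 0.01 * noise_percent * rng.standard_normal(p.shape))
            per_depth[float(dep)] = (x, p)
        profiles[w] = per_depth

    w_big = max(widths)
    r_max = np.sqrt(2.0) * 0.5 * w_big
    r = np.round(np.arange(-r_max, r_max + 0.05, 0.1), 6)
    diag = fff_intensity(np.abs(r), spec.profile_horn_fraction)
    if noise_percent > 0.0:
        diag = diag * (1.0 + 0.01 * noise_percent * rng.standard_normal(diag.shape))
        diag = diag / diag[np.argmin(np.abs(r))]

    ofs = {w: output_factor(w) for w in widths}
    scan = BeamScanSet(
        beam_label=beam_label,
        ssd=float(ssd),
        field_widths=widths,
        pdd_curves=pdd_curves,
        profiles=profiles,
        diagonal_profile=(r, diag),
        output_factors=ofs,
        quality=spec,
    )
    if noise_percent == 0.0:
        scan.validate()
    return scan
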