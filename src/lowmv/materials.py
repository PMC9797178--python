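"""Photon interaction data for the phantom materials.

Semi-empirical cross-section model covering 10 keV - 2.6 MeV, the range
relevant to a 2.5 MV treatment beam:

* Compton (incoherent) scattering: exact Klein-Nishina free-electron cross
  section times the material electron density.  The energy-transfer cross
  section (mean fraction of the photon energy handed to the recoil electron)
  is obtained by numerical quadrature of the Klein-Nishina differential.
* Photoelectric absorption: derived from bundled reference values of the
  water mass attenuation and mass energy-absorption coefficients (standard
  public compilations) by subtracting the Compton energy-transfer component,
  then scaled between materials with the classic Z^4.5 law,
  tau/rho ~ sum_i w_i Z_i^4.5 / A_i.
* Pair production: a small anchored term scaled by sum_i w_i Z_i^2 / A_i,
  negligible below ~1.5 MeV.
* Coherent (Rayleigh) scattering is neglected: it transfers no energy and at
  these energies contributes a few percent to attenuation at most.

Compositions follow the ICRU-46 convention for adult soft tissue and for
cranium- and femur-representative bone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Material",
    "MaterialTable",
    "ELEMENTS",
    "COMPOSITIONS",
    "DEFAULT_DENSITIES",
    "klein_nishina_total",
    "klein_nishina_transfer_fraction",
]

ELECTRON_REST_MEV = 0.510999
AVOGADRO = 6.02214076e23
# classical electron radius squared, cm^2
R_E2 = 7.94079e-26

# (Z, A) for the elements appearing in the ICRU-46 tissues used here.
ELEMENTS: dict[str, tuple[int, float]] = {
    "H": (1, 1.008),
    "C": (6, 12.011),
    "N": (7, 14.007),
    "O": (8, 15.999),
    "Na": (11, 22.990),
    "Mg": (12, 24.305),
    "P": (15, 30.974),
    "S": (16, 32.06),
    "Cl": (17, 35.45),
    "K": (19, 39.098),
    "Ca": (20, 40.078),
    "Fe": (26, 55.845),
}

# Elemental mass fractions.
COMPOSITIONS: dict[str, dict[str, float]] = {
    "water": {"H": 0.1119, "O": 0.8881},
    # ICRU-46 adult soft tissue
    "soft_tissue": {
        "H": 0.102, "C": 0.143, "N": 0.034, "O": 0.708, "Na": 0.002,
        "P": 0.003, "S": 0.003, "Cl": 0.002, "K": 0.003,
    },
    # ICRU-46 skeleton-cranium
    "cranium_bone": {
        "H": 0.050, "C": 0.212, "N": 0.040, "O": 0.435, "Na": 0.001,
        "Mg": 0.002, "P": 0.081, "S": 0.003, "Ca": 0.176,
    },
    # ICRU-46 skeleton-femur (whole)
    "femur_bone": {
        "H": 0.070, "C": 0.345, "N": 0.028, "O": 0.368, "Na": 0.001,
        "Mg": 0.001, "P": 0.055, "S": 0.002, "Ca": 0.129, "Fe": 0.001,
    },
}

DEFAULT_DENSITIES: dict[str, float] = {
    "water": 1.000,
    "soft_tissue": 1.060,
    "cranium_bone": 1.610,
    "femur_bone": 1.330,
}

# Water mass attenuation (mu/rho) and mass energy-absorption (mu_en/rho)
# coefficients, cm^2/g, on a standard energy grid (MeV).  Reference values
# from the usual public photon-data compilations.
_WATER_E = np.array([
    0.010, 0.015, 0.020, 0.030, 0.040, 0.050, 0.060, 0.080, 0.100,
    0.150, 0.200, 0.300, 0.400, 0.500, 0.600, 0.800, 1.000, 1.250,
    1.500, 2.000, 3.000,
])
_WATER_MU = np.array([
    5.329, 1.673, 0.8096, 0.3756, 0.2683, 0.2269, 0.2059, 0.1837, 0.1707,
    0.1505, 0.1370, 0.1186, 0.1061, 0.09687, 0.08956, 0.07865, 0.07072,
    0.06323, 0.05754, 0.04942, 0.03969,
])
_WATER_MU_EN = np.array([
    4.944, 1.374, 0.5503, 0.1557, 0.06947, 0.04223, 0.03190, 0.02597,
    0.02546, 0.02764, 0.02967, 0.03192, 0.03279, 0.03299, 0.03284,
    0.03206, 0.03103, 0.02965, 0.02833, 0.02608, 0.02281,
])

# Pair production in water (nuclear + electron field), cm^2/g, anchored shape.
_PAIR_THRESHOLD = 2.0 * ELECTRON_REST_MEV


def _pair_water(energy: np.ndarray) -> np.ndarray:
    """Approximate water pair-production coefficient (cm^2/g)."""
    e = np.asarray(energy, dtype=float)
    out = np.zeros_like(e)
    above = e > _PAIR_THRESHOLD
    # anchored at ~3.9e-4 cm^2/g at 2 MeV; near-threshold quadratic rise
    out[above] = 4.1e-4 * ((e[above] - _PAIR_THRESHOLD) / (2.0 - _PAIR_THRESHOLD)) ** 2
    return out


def klein_nishina_total(energy_mev: np.ndarray) -> np.ndarray:
    """Total Klein-Nishina cross section per electron (cm^2)."""
    k = np.asarray(energy_mev, dtype=float) / ELECTRON_REST_MEV
    t1 = (1.0 + k) / k**2 * (2.0 * (1.0 + k) / (1.0 + 2.0 * k) - np.log1p(2.0 * k) / k)
    t2 = np.log1p(2.0 * k) / (2.0 * k)
    t3 = (1.0 + 3.0 * k) / (1.0 + 2.0 * k) ** 2
    return 2.0 * np.pi * R_E2 * (t1 + t2 - t3)


def klein_nishina_transfer_fraction(energy_mev: np.ndarray, n_theta: int = 2000) -> np.ndarray:
    """Mean fraction of photon energy transferred to the Compton electron.

    Quadrature over the Klein-Nishina angular distribution.
    """
    e = np.atleast_1d(np.asarray(energy_mev, dtype=float))
    k = e / ELECTRON_REST_MEV
    theta = np.linspace(1e-6, np.pi, n_theta)
    ct = np.cos(theta)
    st2 = 1.0 - ct**2
    # eps = E'/E for each (energy, angle)
    eps = 1.0 / (1.0 + k[:, None] * (1.0 - ct[None, :]))
    dcs = 0.5 * R_E2 * eps**2 * (eps + 1.0 / eps - st2[None, :])
    w = 2.0 * np.pi * np.sin(theta)
    sigma = np.trapezoid(dcs * w[None, :], theta, axis=1)
    sigma_tr = np.trapezoid(dcs * (1.0 - eps) * w[None, :], theta, axis=1)
    return sigma_tr / sigma


def _z_factor(composition: dict[str, float], power: float) -> float:
    return sum(w * ELEMENTS[el][0] ** power / ELEMENTS[el][1] for el, w in composition.items())


def electrons_per_gram(composition: dict[str, float]) -> float:
    return AVOGADRO * sum(w * ELEMENTS[el][0] / ELEMENTS[el][1] for el, w in composition.items())


# Photoelectric Z-dependence exponent (tau/atom ~ Z^4.5 across this range).
_PHOTO_Z_POWER = 4.5


def _water_photoelectric(energy: np.ndarray) -> np.ndarray:
    """Water photoelectric mass coefficient from the bundled reference data.

    tau ~ mu_en - (Compton energy-transfer part); beyond 150 keV, where the
    subtraction loses significance, an E^-3 tail is attached.
    """
    e = np.asarray(energy, dtype=float)
    ne_w = electrons_per_gram(COMPOSITIONS["water"])
    grid = _WATER_E[_WATER_E <= 0.150]
    mu_en = np.interp(grid, _WATER_E, _WATER_MU_EN)
    compton_tr = ne_w * klein_nishina_total(grid) * klein_nishina_transfer_fraction(grid)
    tau_grid = np.clip(mu_en - compton_tr, 1e-7, None)
    tau_150 = tau_grid[-1]
    out = np.where(
        e <= 0.150,
        np.exp(np.interp(np.log(np.clip(e, grid[0], None)), np.log(grid), np.log(tau_grid))),
        tau_150 * (0.150 / e) ** 3,
    )
    # below the table, extrapolate log-log with the first-interval slope
    low = e < grid[0]
    if np.any(low):
        slope = (np.log(tau_grid[1]) - np.log(tau_grid[0])) / (np.log(grid[1]) - np.log(grid[0]))
        out[low] = np.exp(np.log(tau_grid[0]) + slope * (np.log(e[low]) - np.log(grid[0])))
    return out


@dataclass
class Material:
    """Interaction coefficients for one material on a common energy grid."""

    name: str
    density: float  # g/cm^3
    composition: dict[str, float]
    energy: np.ndarray  # MeV
    mu_photo: np.ndarray  # cm^2/g
    mu_compton: np.ndarray  # cm^2/g
    mu_pair: np.ndarray  # cm^2/g
    mu_tr: np.ndarray  # cm^2/g, energy-transfer (collision kerma) coefficient

    @property
    def mu_total(self) -> np.ndarray:
        return self.mu_photo + self.mu_compton + self.mu_pair

    def mu_at(self, energy_mev: float | np.ndarray) -> np.ndarray:
        return np.interp(energy_mev, self.energy, self.mu_total)

    def mu_tr_at(self, energy_mev: float | np.ndarray) -> np.ndarray:
        return np.interp(energy_mev, self.energy, self.mu_tr)


@dataclass
class MaterialTable:
    """Coefficient tables for every material the phantoms can contain."""

    energy: np.ndarray = field(default_factory=lambda: np.geomspace(0.010, 2.6, 220))
    materials: dict[str, Material] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.materials:
            for name in COMPOSITIONS:
                self.add_material(name, COMPOSITIONS[name], DEFAULT_DENSITIES[name])

    def add_material(self, name: str, composition: dict[str, float],
                     density: float) -> Material:
        total = sum(composition.values())
        if abs(total - 1.0) > 5e-3:
            raise ValueError(f"mass fractions for {name!r} sum to {total:.4f}, expected 1")
        comp = {el: w / total for el, w in composition.items()}
        e = self.energy
        ne = electrons_per_gram(comp)
        kn = klein_nishina_total(e)
        f_tr = klein_nishina_transfer_fraction(e)
        mu_c = ne * kn
        zf = _z_factor(comp, _PHOTO_Z_POWER)
        zf_w = _z_factor(COMPOSITIONS["water"], _PHOTO_Z_POWER)
        mu_p = _water_photoelectric(e) * (zf / zf_w)
        z2 = _z_factor(comp, 2.0)
        z2_w = _z_factor(COMPOSITIONS["water"], 2.0)
        mu_pp = _pair_water(e) * (z2 / z2_w)
        with np.errstate(divide="ignore", invalid="ignore"):
            pair_frac = np.where(e > _PAIR_THRESHOLD, 1.0 - _PAIR_THRESHOLD / e, 0.0)
        mu_tr = mu_p + mu_c * f_tr + mu_pp * pair_frac
        mat = Material(name, density, comp, e, mu_p, mu_c, mu_pp, mu_tr)
        self.materials[name] = mat
        return mat

    def __getitem__(self, name: str) -> Material:
        return self.materials[name]

    def names(self) -> list[str]:
        return list(self.materials)
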