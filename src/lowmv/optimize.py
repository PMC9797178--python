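"""Inverse fluence-map optimization.

Minimizes a weighted sum of per-structure penalty terms over nonnegative
bixel weights w, with the dose linear in the weights, d = D w.  The solver
is projected quasi-Newton (L-BFGS-B with a nonnegativity box), deterministic
for fixed inputs and starting point (default w = 1).  DVH-type objectives
use the standard ranked-voxel surrogate, which makes the problem non-convex;
purely quadratic objective sets are convex and reach the global optimum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import minimize

from .dose import InfluenceMatrix

__all__ = ["ObjectiveSpec", "PlanResult", "evaluate_objective",
           "optimize_fluence", "plan_case", "segment_width_range"]

log = logging.getLogger(__name__)

_KINDS = ("squared_underdose", "squared_overdose", "squared_deviation",
          "mean_dose", "max_dose", "min_dose", "dvh_max", "dvh_volume")


@dataclass(frozen=True)
class ObjectiveSpec:
    """One objective/constraint term attached to a structure.

    ``volume`` is the volume fraction parameter of DVH-type terms.  A term
    marked ``constraint=True`` participates with its (typically high) penalty
    like any soft term and is additionally checked post-hoc for satisfaction.
    """

    structure: str
    kind: str
    dose: float  # Gy
    penalty: float
    volume: float | None = None  # fraction in [0, 1] for DVH terms
    constraint: bool = False

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown objective kind {self.kind!r}; known: {_KINDS}")
        if self.dose < 0 or self.penalty < 0:
            raise ValueError("dose level and penalty must be nonnegative")
        if self.kind.startswith("dvh"):
            if self.volume is None or not (0.0 <= self.volume <= 1.0):
                raise ValueError("DVH objectives need a volume fraction in [0, 1]")


def _term(dose_s: np.ndarray, obj: ObjectiveSpec) -> tuple[float, np.ndarray]:
    n = len(dose_s)
    p, level = obj.penalty, obj.dose
    grad = np.zeros(n)
    if obj.kind in ("squared_overdose", "max_dose"):
        over = np.clip(dose_s - level, 0.0, None)
        return p / n * float(np.sum(over**2)), 2.0 * p / n * over
    if obj.kind in ("squared_underdose", "min_dose"):
        under = np.clip(level - dose_s, 0.0, None)
        return p / n * float(np.sum(under**2)), -2.0 * p / n * under
    if obj.kind == "squared_deviation":
        dev = dose_s - level
        return p / n * float(np.sum(dev**2)), 2.0 * p / n * dev
    if obj.kind == "mean_dose":
        m = float(dose_s.mean())
        if m <= level:
            return 0.0, grad
        return p * (m - level) ** 2, np.full(n, 2.0 * p * (m - level) / n)
    # DVH surrogate: allow a fraction `volume` of voxels above the level;
    # penalize the violating voxels between the level and the current dose
    # at the allowed volume (ranked-voxel surrogate).
    d_ref = float(np.quantile(dose_s, 1.0 - obj.volume)) if n else 0.0
    if d_ref <= level:
        return 0.0, grad
    sel = (dose_s > level) & (dose_s <= d_ref)
    grad[sel] = 2.0 * p / n * (dose_s[sel] - level)
    return p / n * float(np.sum((dose_s[sel] - level) ** 2)), grad


def evaluate_objective(
    dose: np.ndarray,
    objectives: list[ObjectiveSpec],
    structures: dict[str, np.ndarray],
) -> tuple[float, np.ndarray]:
    """Total cost and its analytic gradient with respect to the dose vector."""
    dose = np.asarray(dose, float).ravel()
    grad = np.zeros_like(dose)
    cost = 0.0
    for obj in objectives:
        if obj.structure not in structures:
            raise KeyError(f"objective references unknown structure {obj.structure!r}")
        idx = np.flatnonzero(np.asarray(structures[obj.structure]).ravel())
        c, g = _term(dose[idx], obj)
        cost += c
        grad[idx] += g
    return cost, grad


@dataclass
class PlanResult:
    """Optimized plan: weights, achieved dose and diagnostics."""

    weights: np.ndarray
    dose: np.ndarray  # flat voxel dose vector, Gy
    objective_trace: list[float]
    converged: bool
    constraint_report: dict[str, dict] = field(default_factory=dict)
    segment_widths: tuple[float, float] | None = None  # (min, max), cm


class _Stop(Exception):
    pass


def optimize_fluence(
    influence: InfluenceMatrix | sparse.spmatrix,
    objectives: list[ObjectiveSpec],
    structures: dict[str, np.ndarray],
    w0: np.ndarray | None = None,
    max_iter: int = 500,
    rel_tol: float = 1e-5,
    stall_iters: int = 5,
) -> PlanResult:
    """Projected quasi-Newton descent over nonnegative bixel weights.

    Converges when the relative objective change over ``stall_iters``
    accepted iterations falls below ``rel_tol``, or at ``max_iter``.
    """
    D = influence.matrix if isinstance(influence, InfluenceMatrix) else sparse.csc_matrix(influence)
    if not objectives:
        raise ValueError("objectives must be nonempty")
    col_sums = np.asarray(np.abs(D).sum(axis=0)).ravel()
    dead = col_sums == 0
    if dead.any():
        warnings.warn(f"removing {int(dead.sum())} all-zero influence columns",
                      stacklevel=2)
        keep = np.flatnonzero(~dead)
        Dk = D[:, keep]
    else:
        keep = np.arange(D.shape[1])
        Dk = D

    x0 = np.ones(Dk.shape[1]) if w0 is None else np.asarray(w0, float)[keep]

    def fun(w):
        dose = Dk @ w
        cost, gdose = evaluate_objective(dose, objectives, structures)
        return cost, Dk.T @ gdose

    trace: list[float] = []
    best_x = {"x": x0.copy()}

    def callback(xk):
        trace.append(fun(xk)[0])
        best_x["x"] = xk.copy()
        if len(trace) > stall_iters:
            ref = trace[-stall_iters - 1]
            if ref > 0 and (ref - trace[-1]) / ref < rel_tol:
                raise _Stop
        return False

    converged = True
    try:
        res = minimize(fun, x0, jac=True, method="L-BFGS-B",
                       bounds=[(0.0, None)] * len(x0),
                       callback=callback,
                       options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-10})
        x_final = res.x
        converged = bool(res.success or res.status == 1)
    except _Stop:
        x_final = best_x["x"]
    x_final = np.clip(x_final, 0.0, None)
    weights = np.zeros(D.shape[1])
    weights[keep] = x_final
    dose = D @ weights
    trace.append(evaluate_objective(dose, objectives, structures)[0])

    report = {}
    for obj in objectives:
        if not obj.constraint:
            continue
        idx = np.flatnonzero(np.asarray(structures[obj.structure]).ravel())
        ds = dose[idx]
        c, _ = _term(ds, obj)
        report[f"{obj.structure}:{obj.kind}"] = {
            "dose_level": obj.dose, "residual_cost": c, "satisfied": bool(c < 1e-9),
            "max_dose": float(ds.max(initial=0.0)),
        }
        if c >= 1e-9:
            log.warning("hard constraint %s on %s not met; soft-penalty result "
                        "returned", obj.kind, obj.structure)
    return PlanResult(weights=weights, dose=dose, objective_trace=trace,
                      converged=converged, constraint_report=report)


def segment_width_range(setups, weights, threshold: float = 0.1
                        ) -> tuple[float, float] | None:
    """(min, max) width of contiguous open runs in the fluence maps.

    A bixel counts as open when its weight exceeds ``threshold`` times the
    plan maximum; runs are taken along each lattice row (crossplane).
    """
    w_max = float(np.max(weights)) if len(weights) else 0.0
    if w_max <= 0:
        return None
    widths = []
    pos = 0
    for s in setups:
        n = int(s.active.sum())
        fmap = np.zeros(s.active.shape)
        fmap[s.active] = weights[pos:pos + n]
        pos += n
        open_mask = fmap > threshold * w_max
        for row in range(open_mask.shape[1]):
            col = open_mask[:, row]
            run = 0
            for v in np.append(col, False):
                if v:
                    run += 1
                elif run:
                    widths.append(run * s.bixel_width)
                    run = 0
    if not widths:
        return None
    return (float(min(widths)), float(max(widths)))


def plan_case(
    models: dict[str, "object"],
    phantom,
    structures: dict[str, np.ndarray],
    setups,
    objectives: list[ObjectiveSpec],
    cutoff: float = 1e-4,
) -> dict[str, PlanResult]:
    """Run the full inverse-planning chain for each beam model.

    All arms share the phantom, beam angles and objectives - the only
    difference is the beam quality - and each returns a PlanResult keyed by
    the model label.
    """
    from .dose import influence_matrix  # local import for clarity

    results: dict[str, PlanResult] = {}
    for label, model in models.items():
        infl = influence_matrix(model, phantom, setups, mask=structures.get("body"),
                                cutoff=cutoff)
        res = optimize_fluence(infl, objectives, structures)
        res.segment_widths = segment_width_range(setups, res.weights)
        results[label] = res
    return results
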