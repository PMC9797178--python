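"""Fluence optimization: objective gradients, convexity and solver quality."""

import numpy as np
import pytest
from scipy import sparse
from scipy.optimize import nnls

from lowmv.evaluate import integral_dose
from lowmv.optimize import (ObjectiveSpec, evaluate_objective, optimize_fluence,
                            segment_width_range)


def _structures(n):
    return {"all": np.ones(n, dtype=bool)}


def test_uniform_dose_at_prescription_has_zero_cost_and_gradient():
    dose = np.full(50, 60.0)
    objs = [ObjectiveSpec("all", "squared_deviation", 60.0, 10.0)]
    c, g = evaluate_objective(dose, objs, _structures(50))
    assert c == 0.0
    assert np.all(g == 0.0)


def test_mean_dose_gradient_is_constant_over_members():
    dose = np.array([10.0, 20.0, 30.0, 40.0])
    level, penalty = 20.0, 3.0
    objs = [ObjectiveSpec("all", "mean_dose", level, penalty)]
    c, g = evaluate_objective(dose, objs, _structures(4))
    mean = dose.mean()
    assert c == pytest.approx(penalty * (mean - level) ** 2)
    assert np.allclose(g, penalty * 2 * (mean - level) / 4)


def test_cost_is_linear_in_penalties():
    rng = np.random.default_rng(1)
    dose = rng.uniform(0, 80, 100)
    objs = [ObjectiveSpec("all", "squared_overdose", 40.0, 2.0),
            ObjectiveSpec("all", "squared_underdose", 20.0, 5.0)]
    doubled = [ObjectiveSpec(o.structure, o.kind, o.dose, 2 * o.penalty)
               for o in objs]
    c1, _ = evaluate_objective(dose, objs, _structures(100))
    c2, _ = evaluate_objective(dose, doubled, _structures(100))
    assert c2 == pytest.approx(2 * c1, rel=1e-14)


def test_gradients_match_finite_differences():
    rng = np.random.default_rng(2)
    dose = rng.uniform(10, 70, 30)
    structures = {"a": np.arange(30) < 20, "b": np.arange(30) >= 10}
    objs = [ObjectiveSpec("a", "squared_deviation", 50.0, 4.0),
            ObjectiveSpec("b", "max_dose", 40.0, 2.0),
            ObjectiveSpec("a", "mean_dose", 20.0, 1.0)]
    c0, g = evaluate_objective(dose, objs, structures)
    eps = 1e-6
    for i in (0, 5, 15, 25):
        d2 = dose.copy()
        d2[i] += eps
        c1, _ = evaluate_objective(d2, objs, structures)
        assert (c1 - c0) / eps == pytest.approx(g[i], rel=1e-3, abs=1e-8)


def test_unknown_structure_raises():
    with pytest.raises(KeyError):
        evaluate_objective(np.zeros(4),
                           [ObjectiveSpec("ghost", "mean_dose", 1.0, 1.0)],
                           _structures(4))


def test_scalar_closed_form_single_voxel_single_bixel():
    D = sparse.csc_matrix(np.array([[2.0]]))
    objs = [ObjectiveSpec("all", "squared_deviation", 68.0, 1.0)]
    res = optimize_fluence(D, objs, _structures(1))
    assert res.weights[0] == pytest.approx(34.0, rel=1e-5)
    assert res.dose[0] == pytest.approx(68.0, rel=1e-5)


def test_quadratic_problem_matches_exact_nnls_solver():
    """Convex least-squares instance: projected quasi-Newton vs exact NNLS."""
    rng = np.random.default_rng(3)
    D = np.abs(rng.normal(1.0, 0.5, (40, 12)))
    level = 50.0
    objs = [ObjectiveSpec("all", "squared_deviation", level, 1.0)]
    res = optimize_fluence(sparse.csc_matrix(D), objs, _structures(40))
    w_exact, _ = nnls(D, np.full(40, level))
    c_opt, _ = evaluate_objective(D @ res.weights, objs, _structures(40))
    c_exact, _ = evaluate_objective(D @ w_exact, objs, _structures(40))
    assert c_opt <= c_exact * (1 + 1e-3) + 1e-12


def test_different_starting_points_reach_same_convex_optimum():
    rng = np.random.default_rng(4)
    D = sparse.csc_matrix(np.abs(rng.normal(1.0, 0.4, (30, 8))))
    objs = [ObjectiveSpec("all", "squared_deviation", 40.0, 1.0)]
    structures = _structures(30)
    r1 = optimize_fluence(D, objs, structures, w0=np.full(8, 0.1))
    r2 = optimize_fluence(D, objs, structures, w0=np.full(8, 10.0))
    c1 = r1.objective_trace[-1]
    c2 = r2.objective_trace[-1]
    assert abs(c1 - c2) <= 1e-4 * max(c1, c2, 1e-12) + 1e-9


def test_iterates_stay_nonnegative_and_objective_monotone(shallow_case):
    res = shallow_case["2.5MV"]
    assert np.all(res.weights >= 0)
    trace = np.array(res.objective_trace)
    assert np.all(np.diff(trace) <= 1e-9 * np.maximum(trace[:-1], 1e-12))


def test_zero_influence_columns_removed_with_warning():
    D = np.array([[1.0, 0.0], [2.0, 0.0]])
    objs = [ObjectiveSpec("all", "squared_deviation", 10.0, 1.0)]
    with pytest.warns(UserWarning):
        res = optimize_fluence(sparse.csc_matrix(D), objs, _structures(2))
    assert res.weights[1] == 0.0


def test_ptv_coverage_after_optimization(shallow_case):
    """PTV D98 reaches at least 98% of the prescription."""
    for arm in ("2.5MV", "6MV"):
        res = shallow_case[arm]
        ptv_dose = res.dose[shallow_case["structures"]["ptv"].ravel()]
        d98 = np.percentile(ptv_dose, 2.0)
        assert d98 >= 0.98 * shallow_case["prescription"]


def test_integral_dose_direction_shallow_vs_deep(shallow_case, deep_case):
    """The softer 2.5 MV beam spares the body for a shallow target but costs
    integral dose for a deep target, relative to 6 MV."""
    def normalized_integral(case, arm):
        body = case["structures"]["body"].ravel()
        ptv = case["structures"]["ptv"].ravel()
        mean_ptv = case[arm].dose[ptv].mean()
        return integral_dose(case[arm].dose, body) / mean_ptv

    assert (normalized_integral(shallow_case, "2.5MV")
            < normalized_integral(shallow_case, "6MV"))
    assert (normalized_integral(deep_case, "2.5MV")
            > normalized_integral(deep_case, "6MV"))


def test_identical_models_give_identical_plans(shallow_case, model_2p5):
    from lowmv.optimize import plan_case

    case = shallow_case
    results = plan_case({"a": model_2p5, "b": model_2p5}, case["phantom"],
                        case["structures"], case["setups"][:2],
                        case["objectives"])
    assert np.array_equal(results["a"].weights, results["b"].weights)
    assert results["a"].segment_widths == results["b"].segment_widths


def test_segment_width_range_from_fluence_maps():
    s = __import__("lowmv.dose", fromlist=["BeamSetup"]).BeamSetup(
        gantry_deg=0.0, bixel_width=0.5, n_bixels=(4, 2))
    w = np.array([1.0, 0.0, 1.0, 1.0,
                  0.0, 0.0, 1.0, 0.0])
    widths = segment_width_range([s], w)
    assert widths == (0.5, 1.0)


def test_dvh_objective_activates_only_beyond_allowed_volume():
    dose = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
    # at most 40% of voxels may exceed 25 Gy; currently 60% do
    objs = [ObjectiveSpec("all", "dvh_max", 25.0, 1.0, volume=0.4)]
    c, g = evaluate_objective(dose, objs, _structures(5))
    assert c > 0
    assert g[4] == 0.0  # the hottest voxel is inside the allowed volume
    assert g[2] > 0
    # satisfied DVH constraint costs nothing
    objs_ok = [ObjectiveSpec("all", "dvh_max", 45.0, 1.0, volume=0.4)]
    c_ok, g_ok = evaluate_objective(dose, objs_ok, _structures(5))
    assert c_ok == 0.0 and np.all(g_ok == 0.0)
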