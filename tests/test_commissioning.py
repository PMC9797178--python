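"""Commissioning: TMR conversion, intensity tuning, kernel fitting and the
beam-database round trip."""

import dataclasses

import numpy as np
import pytest

from lowmv.commissioning import (IntensityProfile, KernelSet, build_beam_model,
                                 equivalent_square, extract_dd10, extract_dmax,
                                 fit_kernels, load_beam_model, pdd_to_tmr,
                                 tune_intensity_profile)
from lowmv.dose import openfield_pdd, openfield_profile
from lowmv.scans import SAD, generate_beam_scan_set, beam_quality_2p5mv


@pytest.mark.parametrize("pdd10, ssd, dmax, expected", [
    (55.0, 100.0, 0.6, 0.55 * (110.0 / 100.6) ** 2),  # ~0.6577
    (70.0, 100.0, 1.5, 0.70 * (110.0 / 101.5) ** 2),  # ~0.8222
])
def test_pdd_to_tmr_inverse_square_conversion(pdd10, ssd, dmax, expected):
    depths = np.array([0.0, dmax, 10.0])
    pdd = np.array([60.0, 100.0, pdd10])
    d, tmr = pdd_to_tmr((depths, pdd), ssd, dmax)
    assert tmr[1] == pytest.approx(1.0, abs=1e-12)
    assert tmr[2] == pytest.approx(expected, abs=1e-4)


def test_tmr_conversion_is_exactly_invertible():
    depths = np.linspace(0, 30, 301)
    pdd = 100.0 * np.exp(-0.07 * depths) / np.exp(-0.07 * 0.6)
    pdd = 100.0 * pdd / pdd.max()
    _, tmr = pdd_to_tmr((depths, pdd), 100.0, depths[np.argmax(pdd)])
    back = tmr * ((100.0 + depths[np.argmax(pdd)]) / (100.0 + depths)) ** 2 * 100.0
    assert np.allclose(back, pdd, rtol=1e-14)


def test_equivalent_square_reduces_to_identity_for_squares():
    for w in (2.0, 5.0, 10.0, 40.0):
        assert equivalent_square(w, w) == pytest.approx(w, rel=1e-14)
    assert equivalent_square(4.0, 8.0) == pytest.approx(2 * 4 * 8 / 12)


def test_dmax_extraction_parabolic_and_tie_break():
    d = np.arange(0, 3.01, 0.2)
    y = 100 - 30 * (d - 1.03) ** 2
    assert extract_dmax(d, y) == pytest.approx(1.03, abs=0.01)
    flat = np.array([1.0, 2.0, 2.0, 1.0])
    assert extract_dmax(np.array([0, 1, 2, 3.0]), flat) == 1.0  # earlier depth


def test_commissioned_model_reproduces_scan_pdds(model_2p5, scan_2p5):
    grid = np.arange(0.0, 30.001, 0.2)
    for w, (d, p) in scan_2p5.pdd_curves.items():
        rec = openfield_pdd(model_2p5, w, grid)
        assert np.max(np.abs(rec - np.interp(grid, d, p))) < 0.5


def test_six_mv_model_recovers_quality_on_recomputation(model_6):
    grid = np.arange(0.0, 30.001, 0.2)
    pdd = openfield_pdd(model_6, 10.0, grid)
    assert extract_dmax(grid, pdd) == pytest.approx(1.5, abs=0.2)
    assert extract_dd10(grid, pdd) == pytest.approx(70.0, abs=1.0)


def test_intensity_tuning_is_a_fixed_point_on_self_consistent_data(scan_2p5, model_2p5):
    profile, report = tune_intensity_profile(scan_2p5, model_2p5)
    assert report["converged"]
    assert report["max_in_field_deviation_percent"] <= 2.0
    # unchanged within tolerance: compare against the model's tuned profile
    r = np.linspace(0, 20, 30)
    assert np.allclose(profile(r), model_2p5.intensity(r), atol=0.02)


def test_intensity_tuning_improves_a_perturbed_profile(scan_2p5, model_2p5):
    perturbed = IntensityProfile(
        radius=model_2p5.intensity.radius.copy(),
        value=model_2p5.intensity.value.copy())
    perturbed.value[2] *= 1.05  # control point well inside the 80% region
    start = dataclasses.replace(model_2p5, intensity=perturbed)

    def dev(model):
        worst = 0.0
        for w, per_depth in scan_2p5.profiles.items():
            for dep, (x, meas) in per_depth.items():
                comp = openfield_profile(model, w, dep, x)
                sel = meas >= 80.0
                worst = max(worst, float(np.max(np.abs(comp[sel] - meas[sel]))))
        return worst

    tuned, _ = tune_intensity_profile(scan_2p5, start)
    assert dev(dataclasses.replace(start, intensity=tuned)) < dev(start)


def test_kernel_fit_recovers_single_component_width(scan_2p5):
    """Parameter recovery: profiles built from one Gaussian kernel."""
    from lowmv.commissioning import _profile_model

    sigma_true = 0.42
    flat = IntensityProfile(radius=np.array([0.0, 40.0]), value=np.array([1.0, 1.0]))
    synthetic = dataclasses.replace(scan_2p5)
    synthetic.profiles = {}
    for w in (4.0, 10.0, 20.0):
        per = {}
        for dep in (1.0, 10.0):
            mag = (100.0 + dep) / SAD
            x = np.arange(-0.75 * w * mag - 3, 0.75 * w * mag + 3, 0.1)
            per[dep] = (x, _profile_model(x, w, dep, 100.0, SAD,
                                          np.array([1.0]), np.array([sigma_true]),
                                          flat))
        synthetic.profiles[w] = per
    kernels, _ = fit_kernels(synthetic, None, flat, n_components=1)
    assert kernels.sigmas[0] == pytest.approx(sigma_true, rel=0.01)


def test_fitted_kernel_weights_sum_to_one(model_2p5):
    assert model_2p5.kernels.weights.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(np.diff(model_2p5.kernels.sigmas) > 0)


def test_beam_database_round_trip(tmp_path, model_2p5):
    path = model_2p5.save(tmp_path / "beam.h5")
    back = load_beam_model(path)
    assert back.beam_label == model_2p5.beam_label
    assert np.allclose(back.tmr_table.values, model_2p5.tmr_table.values)
    assert back.tmr_table.d_max == model_2p5.tmr_table.d_max
    assert back.output_factors == model_2p5.output_factors
    assert np.allclose(back.intensity.value, model_2p5.intensity.value)
    assert np.allclose(back.kernels.sigmas, model_2p5.kernels.sigmas)
    assert back.residual_report == model_2p5.residual_report


def test_kernel_set_invariants_enforced():
    with pytest.raises(ValueError):
        KernelSet(weights=np.array([0.6, 0.6]), sigmas=np.array([0.3, 1.0])).validate()
    with pytest.raises(ValueError):
        KernelSet(weights=np.array([0.5, 0.5]), sigmas=np.array([1.0, 0.3])).validate()
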