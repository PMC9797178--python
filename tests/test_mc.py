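"""Monte Carlo transport: attenuation physics, estimator statistics,
spectrum tuning behavior and the engine cross-checks."""

import numpy as np
import pytest

from lowmv.evaluate import gamma_index
from lowmv.materials import MaterialTable
from lowmv.mc import (SourceModel, bone_experiment, transport, tune_spectrum)
from lowmv.phantoms import water_cube
from lowmv.spectra import Spectrum, generate_spectrum


def _mono(e):
    return Spectrum(bin_edges=np.array([e - 1e-3, e + 1e-3]),
                    fluence=np.array([1.0]))


@pytest.fixture(scope="module")
def water():
    return water_cube(voxel=0.5)


def test_primary_survival_follows_beer_lambert(water):
    """Uncollided fraction vs depth matches exp(-mu d) within 3 sigma for a
    narrow monoenergetic beam."""
    e = 0.8
    n = 200_000
    tg = transport(_mono(e), water, SourceModel(field_width=0.4),
                   n_histories=n, seed=2)
    mu = float(MaterialTable()["water"].mu_at(e))
    n0 = tg.uncollided[0]
    for depth in (2.0, 5.0, 10.0):
        k = int(depth / 0.2)
        observed = tg.uncollided[k - 1] / n0
        expected = np.exp(-mu * (k * 0.2 - 0.2))
        sigma = np.sqrt(expected * (1 - expected) / n0)
        assert abs(observed - expected) < 3.5 * sigma + 1e-4


def test_same_seed_reproduces_identical_tallies(water):
    a = transport(generate_spectrum(), water, n_histories=50_000, seed=11)
    b = transport(generate_spectrum(), water, n_histories=50_000, seed=11)
    assert np.array_equal(a.dose, b.dose)
    assert a.energy_deposited == b.energy_deposited


def test_energy_bookkeeping_deposited_not_above_emitted(water):
    tg = transport(generate_spectrum(), water, n_histories=100_000, seed=3)
    assert 0.0 < tg.energy_deposited <= tg.energy_emitted
    assert tg.energy_emitted == pytest.approx(generate_spectrum().mean_energy,
                                              rel=0.01)


def test_uncertainty_scales_as_inverse_sqrt_histories(water):
    """16x more histories should shrink the batch uncertainty ~4x; the
    ratio is pooled over two seed pairs to tame estimator noise."""
    spec = generate_spectrum()
    sel = slice(5, 60)  # well-sampled depth range
    ratios = []
    for seed_small, seed_large in ((5, 6), (7, 8)):
        small = transport(spec, water, n_histories=125_000, seed=seed_small,
                          n_batches=20)
        large = transport(spec, water, n_histories=2_000_000, seed=seed_large,
                          n_batches=20)
        ratios.append(np.mean(small.rel_uncertainty[sel])
                      / np.mean(large.rel_uncertainty[sel]))
    pooled = float(np.sqrt(ratios[0] * ratios[1]))
    assert 4.0 == pytest.approx(pooled, rel=0.2)


def test_history_count_precondition(water):
    with pytest.raises(ValueError):
        transport(generate_spectrum(), water, n_histories=100, seed=1)


def test_unknown_material_rejected():
    ph = water_cube(extent=6.0, voxel=0.5)
    ph.material_names = ["unobtainium"]
    with pytest.raises(ValueError):
        transport(generate_spectrum(), ph, n_histories=20_000, seed=1)


def test_null_bone_insert_gives_zero_increment():
    """Bone region painted as soft tissue: paired runs are identical."""
    r = bone_experiment("null_femur", generate_spectrum(),
                        n_histories=100_000, seed=4, voxel=0.5)
    assert r["in_bone_increment_mean_percent"] == pytest.approx(0.0, abs=1e-9)
    assert r["dd10_change"] == pytest.approx(0.0, abs=1e-9)


def test_bone_increment_grows_with_low_energy_fluence():
    """Photoelectric mechanism: enriching the sub-200 keV fluence raises the
    in-bone dose increment."""
    edges = np.array([0.05, 0.15, 1.0, 1.4])
    soft = Spectrum(bin_edges=edges, fluence=np.array([0.45, 0.0, 0.55]))
    hard = Spectrum(bin_edges=edges, fluence=np.array([0.05, 0.0, 0.95]))
    r_soft = bone_experiment("cranium", soft, n_histories=400_000, seed=8,
                             voxel=0.5)
    r_hard = bone_experiment("cranium", hard, n_histories=400_000, seed=8,
                             voxel=0.5)
    assert (r_soft["in_bone_increment_mean_percent"]
            > r_hard["in_bone_increment_mean_percent"] + 1.0)


def test_tuning_is_fixed_point_on_self_generated_reference(water):
    """Reference PDD produced by the initial spectrum itself: the tuned
    spectrum comes back essentially unchanged."""
    init = generate_spectrum()
    ref_run = transport(init, water, n_histories=1_500_000, seed=21)
    z = ref_run.z_centers
    tuned, report = tune_spectrum(init, (z, ref_run.pdd), budget=4_000_000,
                                  seed=22, n_groups=10)
    assert tuned.mean_energy == pytest.approx(init.mean_energy, abs=0.06)
    scales = np.asarray(report["group_scales"])
    assert np.all((scales > 0.6) & (scales < 1.6))


def test_tuning_hardens_spectrum_for_harder_reference(water):
    """Beam-hardening monotonicity on a two-line toy spectrum."""
    edges = np.array([0.29, 0.31, 1.24, 1.26])
    start = Spectrum(bin_edges=edges, fluence=np.array([0.5, 0.0, 0.5]))
    harder = Spectrum(bin_edges=edges, fluence=np.array([0.25, 0.0, 0.75]))
    ref_a = transport(start, water, n_histories=1_000_000, seed=31)
    ref_b = transport(harder, water, n_histories=1_000_000, seed=31)
    z = ref_a.z_centers
    tune_kw = dict(budget=2_000_000, seed=32, n_groups=8, smoothness=0.03)
    tuned_a, _ = tune_spectrum(start, (z, ref_a.pdd), **tune_kw)
    tuned_b, _ = tune_spectrum(start, (z, ref_b.pdd), **tune_kw)
    assert tuned_b.mean_energy > tuned_a.mean_energy


def test_tuned_spectrum_keeps_published_beam_characteristics(tuned_mc):
    tuned = tuned_mc["spectrum"]
    assert 0.45 <= tuned.mean_energy <= 0.55
    lo, hi = tuned.mode_bin
    assert lo <= 0.12 <= hi
    assert tuned_mc["report"]["converged"]


def test_small_field_engine_mc_cross_check(tuned_mc, model_2p5):
    """2x2 cm^2 water PDD: pencil-beam engine vs MC, 2%/2 mm gamma beyond
    the buildup region."""
    from lowmv.dose import openfield_pdd

    z, _ = tuned_mc["reference"]
    tg = transport(tuned_mc["spectrum"], water_cube(voxel=0.5),
                   SourceModel(field_width=2.0), n_histories=2_000_000,
                   seed=1, buildup_kernel=tuned_mc["kernel"])
    eng = openfield_pdd(model_2p5, 2.0, z)
    sel = z > 1.0
    g = gamma_index((z[sel], eng[sel]), (z, tg.pdd))
    assert g.pass_fraction == 1.0
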