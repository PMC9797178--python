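"""Pencil-beam engine: linearity, normalization, heterogeneity handling and
influence-matrix assembly."""

import numpy as np
import pytest

from lowmv.dose import (BeamSetup, aperture_equivalent_square, beam_geometry,
                        beamlet_dose, influence_matrix, openfield_cax_dose,
                        openfield_pdd)
from lowmv.evaluate import gamma_index
from lowmv.phantoms import PhantomSpec, generate_phantom, water_cube


@pytest.fixture(scope="module")
def small_water():
    return water_cube(extent=12.0, voxel=0.4)


@pytest.fixture(scope="module")
def small_setup():
    return BeamSetup(gantry_deg=0.0, isocenter=(0.0, 0.0, 5.0),
                     bixel_width=1.0, n_bixels=(4, 4))


@pytest.fixture(scope="module")
def small_influence(model_2p5, small_water, small_setup):
    return influence_matrix(model_2p5, small_water, [small_setup])


def test_beamlet_sum_on_axis_equals_open_field_dose(model_2p5):
    """erf-box beamlet kernels are a partition of unity: summing all
    beamlets of an open 10x10 field reproduces the open-field CAX dose."""
    ph = water_cube(extent=8.0, voxel=0.2)
    setup = BeamSetup(gantry_deg=0.0, isocenter=(0.0, 0.0, 0.0),
                      bixel_width=0.5, n_bixels=(20, 20))
    xx, yy, _ = ph.center_grids()
    # single voxel column closest to the central axis (centers at 0.1 cm)
    cax_mask = (np.abs(xx - 0.1) < 0.01) & (np.abs(yy - 0.1) < 0.01)
    geom = beam_geometry(model_2p5, ph, setup, mask=cax_mask)
    total = np.zeros(int(cax_mask.sum()))
    id_order = {vid: i for i, vid in enumerate(geom.voxel_ids)}
    for j in range(400):
        ids, vals = beamlet_dose(model_2p5, geom, j, cutoff=0.0)
        for vid, v in zip(ids, vals):
            total[id_order[vid]] += v
    depths = ph.centers(2)
    ref = openfield_cax_dose(model_2p5, 10.0, depths)
    assert np.allclose(total, ref, rtol=2e-3)


def test_dose_is_linear_in_fluence_weights(small_influence):
    rng = np.random.default_rng(0)
    w1 = rng.uniform(0, 2, small_influence.n_bixels)
    w2 = rng.uniform(0, 2, small_influence.n_bixels)
    lhs = small_influence.dose(1.7 * w1 + 0.3 * w2)
    rhs = 1.7 * small_influence.dose(w1) + 0.3 * small_influence.dose(w2)
    assert np.allclose(lhs, rhs, rtol=1e-12, atol=1e-300)


def test_unit_weights_reproduce_row_sums(small_influence):
    d = small_influence.dose(np.ones(small_influence.n_bixels))
    rows = np.asarray(small_influence.matrix.sum(axis=1)).ravel()
    assert np.allclose(d.ravel(), rows, rtol=1e-12)


def test_heterogeneity_correction_is_identity_in_water(model_2p5, small_water, small_setup):
    het = influence_matrix(model_2p5, small_water, [small_setup], heterogeneity=True)
    hom = influence_matrix(model_2p5, small_water, [small_setup], heterogeneity=False)
    assert np.allclose(het.matrix.toarray(), hom.matrix.toarray(), rtol=1e-9)


def test_beam_order_permutation_only_permutes_columns(model_2p5, small_water):
    s1 = BeamSetup(gantry_deg=0.0, isocenter=(0, 0, 5.0), bixel_width=1.0,
                   n_bixels=(3, 3))
    s2 = BeamSetup(gantry_deg=90.0, isocenter=(0, 0, 5.0), bixel_width=1.0,
                   n_bixels=(3, 3))
    a = influence_matrix(model_2p5, small_water, [s1, s2])
    b = influence_matrix(model_2p5, small_water, [s2, s1])
    n = 9
    assert np.allclose(a.matrix[:, :n].toarray(), b.matrix[:, n:].toarray())
    assert np.allclose(a.matrix[:, n:].toarray(), b.matrix[:, :n].toarray())


def test_inverse_square_scaling_of_open_field_dose(model_2p5):
    """At fixed radiological depth the CAX dose scales as 1/(SSD+d)^2."""
    d = np.array([5.0])
    base = openfield_cax_dose(model_2p5, 10.0, d, ssd=100.0)[0]
    for ssd in (90.0, 95.0, 105.0, 110.0):
        dose = openfield_cax_dose(model_2p5, 10.0, d, ssd=ssd)[0]
        expected = base * ((100.0 + d[0]) / (ssd + d[0])) ** 2
        assert dose == pytest.approx(expected, rel=5e-3)


def test_recomputed_pdds_pass_gamma_against_scan(model_2p5, scan_2p5):
    grid = np.arange(0.0, 30.001, 0.2)
    for w, (d, p) in scan_2p5.pdd_curves.items():
        crit = (3.0, 0.3) if w >= 40.0 else (2.0, 0.2)
        rec = openfield_pdd(model_2p5, w, grid)
        g = gamma_index((d, p), (grid, rec), dose_percent=crit[0], dta=crit[1])
        assert g.pass_fraction == 1.0


def test_missing_ray_yields_empty_column(model_2p5):
    ph = water_cube(extent=6.0, voxel=0.5)
    setup = BeamSetup(gantry_deg=0.0, isocenter=(50.0, 50.0, 3.0),
                      bixel_width=0.5, n_bixels=(2, 2))
    mask = np.zeros(ph.shape, dtype=bool)
    mask[0, 0, 0] = True  # far away from the beam corridor
    geom = beam_geometry(model_2p5, ph, setup, mask=mask)
    ids, vals = beamlet_dose(model_2p5, geom, 0)
    assert len(vals) == 0 or vals.max() < 1e-12


def test_aperture_equivalent_square():
    active = np.ones((4, 4), dtype=bool)
    assert aperture_equivalent_square(active, 0.5) == pytest.approx(2.0)
    rect = np.ones((8, 2), dtype=bool)
    assert aperture_equivalent_square(rect, 0.5) == pytest.approx(2 * 4 * 1 / 5)


def test_memory_guard_rejects_oversized_problems(model_2p5, small_water):
    setup = BeamSetup(gantry_deg=0.0, isocenter=(0, 0, 5.0),
                      bixel_width=0.1, n_bixels=(100, 100))
    with pytest.raises(MemoryError):
        influence_matrix(model_2p5, small_water, [setup], max_entries=1e3)


def test_angle_validation():
    with pytest.raises(ValueError):
        BeamSetup(gantry_deg=400.0)
    with pytest.raises(ValueError):
        BeamSetup(gantry_deg=0.0, bixel_width=-0.5)
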