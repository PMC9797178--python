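"""Shared fixtures: commissioned beam models, the tuned MC spectrum and a
pair of small inverse plans.  The expensive fixtures are session-scoped so
the whole suite pays for commissioning and spectrum tuning once."""

import logging

import numpy as np
import pytest

from lowmv.commissioning import build_beam_model
from lowmv.dose import BeamSetup, influence_matrix, openfield_pdd
from lowmv.mc import tune_spectrum
from lowmv.optimize import ObjectiveSpec, optimize_fluence
from lowmv.phantoms import planning_phantom
from lowmv.scans import (beam_quality_2p5mv, beam_quality_6mv,
                         generate_beam_scan_set)
from lowmv.spectra import generate_spectrum

logging.getLogger("lowmv").setLevel(logging.ERROR)

PDD_GRID = np.arange(0.0, 30.001, 0.2)
TALLY_Z = (np.arange(150) + 0.5) * 0.2


@pytest.fixture(scope="session")
def scan_2p5():
    return generate_beam_scan_set(beam_quality_2p5mv(), seed=0, beam_label="2.5MV")


@pytest.fixture(scope="session")
def scan_6():
    return generate_beam_scan_set(beam_quality_6mv(), seed=0, beam_label="6MV")


@pytest.fixture(scope="session")
def model_2p5(scan_2p5):
    return build_beam_model(scan_2p5)


@pytest.fixture(scope="session")
def model_6(scan_6):
    return build_beam_model(scan_6)


@pytest.fixture(scope="session")
def engine_pdd_2p5(model_2p5):
    """Recomputed 10x10 water PDD of the commissioned 2.5 MV beam on the
    MC tally depth grid."""
    return TALLY_Z, openfield_pdd(model_2p5, 10.0, TALLY_Z)


@pytest.fixture(scope="session")
def tuned_mc(engine_pdd_2p5):
    """Tuned 2.5 MV spectrum + buildup kernel matched to the engine."""
    z, ref = engine_pdd_2p5
    tuned, report = tune_spectrum(generate_spectrum(), (z, ref), seed=1)
    return {"spectrum": tuned, "kernel": report["buildup_kernel"],
            "report": report, "reference": (z, ref)}


def _plan_arm(model, phantom, structures, setups, objectives):
    infl = influence_matrix(model, phantom, setups, mask=structures["body"])
    return optimize_fluence(infl, objectives, structures)


def _paired_case(target_depth, model_a, model_b):
    phantom, structures = planning_phantom(target_depth=target_depth, voxel=0.6,
                                           body_semi_axes=(9.0, 9.0, 8.0))
    xx, yy, zz = phantom.center_grids()
    ids = np.flatnonzero(structures["ptv"].ravel())
    iso = (float(xx.ravel()[ids].mean()), float(yy.ravel()[ids].mean()),
           float(zz.ravel()[ids].mean()))
    setups = [BeamSetup(gantry_deg=g, isocenter=iso, bixel_width=1.0,
                        n_bixels=(5, 5))
              for g in (0.0, 72.0, 144.0, 216.0, 288.0)]
    rx = 60.0
    objectives = [
        ObjectiveSpec("ptv", "squared_deviation", rx, 100.0),
        ObjectiveSpec("oar_distal", "squared_overdose", 0.3 * rx, 30.0),
        ObjectiveSpec("body", "squared_overdose", 1.05 * rx, 10.0),
    ]
    return {
        "phantom": phantom, "structures": structures, "setups": setups,
        "objectives": objectives, "prescription": rx,
        "2.5MV": _plan_arm(model_a, phantom, structures, setups, objectives),
        "6MV": _plan_arm(model_b, phantom, structures, setups, objectives),
    }


@pytest.fixture(scope="session")
def shallow_case(model_2p5, model_6):
    return _paired_case(3.0, model_2p5, model_6)


@pytest.fixture(scope="session")
def deep_case(model_2p5, model_6):
    return _paired_case(7.5, model_2p5, model_6)
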