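"""Inverse-planned 2.5 MV vs 6 MV comparison on a synthetic planning phantom.

Optimizes the same five-beam arrangement and objectives for both beam
qualities on a shallow (3 cm) target and prints the paired dose indices:
PTV coverage should be equivalent while the integral dose differs with beam
energy.  Runtime: roughly a minute.
"""

import numpy as np

from lowmv import (BeamSetup, ObjectiveSpec, beam_quality_2p5mv,
                   beam_quality_6mv, build_beam_model, dose_indices,
                   generate_beam_scan_set, influence_matrix, integral_dose,
                   optimize_fluence, planning_phantom)

models = {
    "2.5MV": build_beam_model(generate_beam_scan_set(beam_quality_2p5mv(), seed=0)),
    "6MV": build_beam_model(generate_beam_scan_set(beam_quality_6mv(), seed=0)),
}
phantom, structures = planning_phantom(target_depth=3.0, voxel=0.6,
                                       body_semi_axes=(9.0, 9.0, 8.0))
xx, yy, zz = phantom.center_grids()
ids = structures["ptv"].ravel().nonzero()[0]
iso = (xx.ravel()[ids].mean(), yy.ravel()[ids].mean(), zz.ravel()[ids].mean())
setups = [BeamSetup(gantry_deg=g, isocenter=iso, bixel_width=1.0,
                    n_bixels=(5, 5)) for g in (0, 72, 144, 216, 288)]
rx = 60.0
objectives = [
    ObjectiveSpec("ptv", "squared_deviation", rx, 100.0),
    ObjectiveSpec("oar_distal", "squared_overdose", 0.3 * rx, 30.0),
    ObjectiveSpec("body", "squared_overdose", 1.05 * rx, 10.0),
]

print(f"prescription {rx:.0f} Gy to a 3 cm-deep PTV, 5 coplanar beams\n")
for label, model in models.items():
    infl = influence_matrix(model, phantom, setups, mask=structures["body"])
    plan = optimize_fluence(infl, objectives, structures)
    idx = dose_indices(plan.dose, structures).per_structure
    body_int = integral_dose(plan.dose, structures["body"])
    print(f"{label}: PTV D98 = {idx['ptv']['D98']:.1f} Gy, "
          f"D2 = {idx['ptv']['D2']:.1f} Gy, "
          f"distal-OAR Dmean = {idx['oar_distal']['Dmean']:.1f} Gy, "
          f"integral dose = {body_int:.2f} Gy")
print("\n  -> both energies cover the PTV; for this shallow target the "
      "2.5 MV beam's faster fall-off deposits less total energy in the body.")
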