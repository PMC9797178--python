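"""Per-beamlet dose with radiological-pathlength heterogeneity correction.

Computes a small influence matrix in a soft-tissue phantom containing a
femur-like bone block and shows how the density-weighted path length shifts
the depth dose of a beamlet passing through bone.
"""

import numpy as np

from lowmv import (BeamSetup, beam_quality_2p5mv, build_beam_model,
                   femur_block_phantom, generate_beam_scan_set,
                   influence_matrix, radiological_depth)

model = build_beam_model(generate_beam_scan_set(beam_quality_2p5mv(), seed=0))
phantom = femur_block_phantom(extent=16.0, voxel=0.4)

trace = radiological_depth(phantom, (0.0, 0.0, -100.0), (0.0, 0.0, 10.0))
print(f"central ray to 10 cm depth: geometric path {trace.geometric_length:.2f} cm, "
      f"radiological depth {trace.radiological_depth:.2f} cm")
print("  -> 4 cm of rho=1.33 bone plus 6 cm of rho=1.06 soft tissue add "
      "about 1.7 cm of water-equivalent depth.")

setup = BeamSetup(gantry_deg=0.0, isocenter=(0.0, 0.0, 6.0),
                  bixel_width=1.0, n_bixels=(3, 3))
het = influence_matrix(model, phantom, [setup], heterogeneity=True)
hom = influence_matrix(model, phantom, [setup], heterogeneity=False)
w = np.ones(het.n_bixels)
dose_het = het.dose(w)
dose_hom = hom.dose(w)
zc = phantom.centers(2)
icax = np.argmin(np.abs(phantom.centers(0) - 0.2))
for depth in (2.0, 6.0, 10.0, 14.0):
    iz = np.argmin(np.abs(zc - depth))
    a = dose_het[icax, icax, iz]
    b = dose_hom[icax, icax, iz]
    print(f"  depth {depth:4.1f} cm: corrected {a:.4f} Gy vs uncorrected "
          f"{b:.4f} Gy ({100 * (a / b - 1):+.1f}%)")
print("  -> beyond the bone block the corrected dose is lower: the beamlet "
      "has spent more attenuation reaching the same geometric depth.")
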