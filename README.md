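# lowmv — treatment-planning feasibility toolkit for low-megavoltage photon beams

`lowmv` is a research pipeline for studying whether a 2.5 MV
flattening-filter-free (FFF) photon beam — the imaging beam available on
modern linear accelerators — can produce clinically meaningful treatment
plans, compared against a conventional 6 MV therapy beam.  It is written
for medical-physics researchers who want a self-contained, scriptable
implementation of the full chain:

1. **Synthetic beam data** (`lowmv.scans`, `lowmv.phantoms`,
   `lowmv.spectra`): water-tank-style scan sets (central-axis PDDs, lateral
   profiles, output factors, diagonal fluence profile), voxel phantoms with
   ICRU-46 tissue compositions, and analytic bremsstrahlung spectra.  The
   2.5 MV beam is pinned to d_max = 0.6 cm and %dd10 = 55, the 6 MV beam to
   1.5 cm and 70.
2. **Commissioning** (`lowmv.commissioning`): PDD → TMR conversion with the
   peak scatter factor set to unity,
   `TMR(d) = PDD(d)/100 · ((SSD+d)/(SSD+d_max))²`,
   iterative tuning of the FFF intensity profile, and least-squares fitting
   of decomposed lateral pencil-beam kernels (a sum of Gaussians).
3. **Pencil-beam dose engine** (`lowmv.dose`, `lowmv.raytrace`): per-beamlet
   dose `D_ij` with heterogeneity handled through the radiological path
   length `d = Σ l_ijk ρ_ijk` (exact Siddon-style voxel traversal), assembled
   into a sparse influence matrix.
4. **Inverse planning** (`lowmv.optimize`): fluence weights `w ≥ 0`
   minimizing per-structure penalty objectives of the dose `d_i = Σ_j D_ij w_j`
   by projected quasi-Newton descent.
5. **Evaluation** (`lowmv.evaluate`): cumulative DVHs, D98%/D2%/Dmean/Dmax,
   dose to the hottest v cm³, integral dose (mean dose over the body),
   average radiological depth, and the global gamma index
   `γ = min √((Δd/ΔD)² + (Δr/DTA)²)` with no low-dose threshold.
6. **Monte Carlo benchmark** (`lowmv.mc`, `lowmv.materials`): voxel photon
   transport (Woodcock tracking, exact Klein-Nishina Compton sampling,
   collision-kerma scoring in 1.0 × 1.0 × 0.2 cm³ central-axis tally voxels)
   used to tune the 2.5 MV spectrum against the engine's water depth dose
   and to quantify dose in and behind cranium- and femur-like bone inserts.

The study design this mirrors — beam arrangement tables, the 2%/2 mm gamma
validation, the spectrum-tuning-to-PDD procedure, and the slab-phantom bone
experiments — is described in `docs/methods.md` together with every model
assumption and its limits.

## Worked example

```python
import numpy as np
from lowmv import (beam_quality_2p5mv, build_beam_model, extract_dmax,
                   extract_dd10, generate_beam_scan_set, openfield_pdd)

scan = generate_beam_scan_set(beam_quality_2p5mv(), seed=0)
model = build_beam_model(scan)
grid = np.arange(0.0, 30.001, 0.2)
pdd = openfield_pdd(model, 10.0, grid)
print(extract_dmax(grid, pdd), extract_dd10(grid, pdd))
```

prints `0.64 55.0` — the commissioned model returns the 2.5 MV beam quality
(depth of maximum dose 0.6 cm, 55% depth dose at 10 cm) to within the 2 mm
depth grid.  The scripts in `examples/` walk through each capability; e.g.
`examples/03_paired_inverse_plans.py` optimizes the same five-beam plan for
both energies on a phantom with a 3 cm-deep target and prints

```
2.5MV: PTV D98 = 59.7 Gy, D2 = 60.3 Gy, ... integral dose = 5.98 Gy
6MV:   PTV D98 = 59.8 Gy, D2 = 60.2 Gy, ... integral dose = 6.34 Gy
```

— equivalent target coverage, with the 2.5 MV arm depositing ~6% less
integral dose for this shallow target (the ordering reverses for deep
targets; see `tests/test_optimize.py`).

A thin CLI wraps the same library calls:

```bash
lowmv synth --beam 2.5MV --out-dir scan25
lowmv commission --scan-dir scan25 --out model25.h5
lowmv validate --model model25.h5 --scan-dir scan25
lowmv study --config study.yaml --out-dir out
```

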