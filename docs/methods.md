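# Methods

This note documents the models behind `lowmv`: what each stage assumes, the
parameters that matter, how the synthetic data generator was calibrated, and
what the passing tests do and do not demonstrate about real beams.

## Synthetic beam data

The generator emulates a water-tank commissioning session for two beam
qualities: a 2.5 MV FFF imaging-class beam (d_max 0.6 cm, %dd10 55, surface
dose 70%, strongly centre-peaked fluence falling 45% by 20 cm off-axis) and
a conventional flattened 6 MV beam (1.5 cm, 70%, 55%, near-flat).  Field
sizes 4–40 cm at SSD 100 cm, PDDs on a 1 mm grid to 30 cm, profiles at
d_max, 5, 10 and 20 cm.

Depth dose is a two-exponential buildup core times a scatter-volume factor,

    pdd(d, W) ∝ [e^{−μd} − c·e^{−βd}] · (1 + B·b(d)) · (1 + A(W)s(d)) / (1 + A(10)s(d)),

with (μ, β, c) solved per beam quality so the 10×10 curve attains its
maximum at d_max, the requested %dd10 at 10 cm, and the requested surface
dose at d = 0.  The generalization of the plain two-exponential (the `c`
parameter) exists precisely to give the curve a finite surface dose.

The scatter constants are **not** free knobs: they were calibrated once
against the package's own Monte Carlo water depth-dose curves and then
frozen.  Two separate calibrations are composed because they answer two
separate questions:

* the reference-field factor `1 + 0.258·(1 − e^{−d/4.5})` reproduces the
  absolute 10×10 kerma depth shape (so that a *physical* photon spectrum
  can match the commissioned curve during tuning), and
* the field-size modulation with `s(d) = 1 − e^{−(d/15.03)^{1.14}}` and
  `A(W) = −0.1511 + 5.7593·W/(W + 62.4)` reproduces the MC field-to-field
  depth-dose *ratios* from 2 to 40 cm (so that the engine's TMR
  extrapolation to a 2×2 field agrees with the MC; A(W) is negative for
  very small fields, where the beam decays faster than the broad-beam
  effective attenuation).

Caveat: the MC source has uniform fluence across the collimated aperture,
so the synthetic large-field (20–40 cm) %dd10 values (~66/78) are higher
than a real FFF machine's, whose fluence halves toward the 40 cm field
edge.  No cross-check in this package depends on fields above 10 cm versus
the MC.

Lateral profiles are an error-function penumbra (80–20 width 0.6/0.7 cm at
isocenter) plus a 4% broad scatter tail (σ 2.5 cm) times the FFF fluence
factor; output factors follow `1 + 0.05·ln(W/10)`.  Noise is off by default
and the generator is byte-reproducible per seed.  What the generator does
*not* emulate: detector volume averaging, real measurement noise spectra,
electron contamination, arbitrary SSDs per curve.

## Commissioning

PDD→TMR uses the inverse-square-only conversion (all peak-scatter-factor
ratios set to one); it is exactly invertible, so recomputed PDDs reproduce
the inputs to interpolation accuracy (the measured worst-case deviation
across all fields is ~0.1 points, and all fields pass global 2%/2 mm gamma,
3%/3 mm at 40 cm).  d_max is extracted by parabolic interpolation through
the three highest samples (exact ties resolve to the smaller depth); depth
and field-size interpolation are linear, equivalent squares use 4·Area/
Perimeter, and equivalent squares below the smallest commissioned field are
linearly extrapolated down to 2 cm.

The intensity profile is seeded from the diagonal scan and tuned by
coordinate-wise multiplicative updates (10 control radii, ratio of measured
to computed profile, tol 1e−3, max 50 iterations); on self-consistent data
it is a fixed point and terminates with in-field (≥80% isodose) deviations
≈0.4%, well under the 2% criterion.  Lateral kernels are three Gaussians
(weights summing to one, widths strictly increasing by construction) fitted
to all profiles by least squares; output factors are carried as targets and
their residuals reported in the model.

## Pencil-beam engine

Beamlet dose is

    calibration · OF(eq. square) · TMR(d_rad, eq. square) · intensity(r) ·
    (SAD/dist)² · Σ_c w_c·BoxKernel_c ,

evaluated in isocenter-plane coordinates so kernel widths scale with the
geometric magnification.  The erf-box beamlet integrals form a partition of
unity over the fluence lattice — summing an open field's beamlets
reproduces the commissioned TMR on the axis exactly, which is what makes
the commissioning round trip tight.  Heterogeneity enters only through the
radiological path length (dose is reported to water): exact parametric
voxel traversal for single rays, and a vectorized midpoint integrator
(step = half the smallest voxel) for whole-grid depth maps, which agrees
with the exact tracer to <0.1% and is exact in homogeneous phantoms.
Column entries below 10⁻⁴ of the column maximum are dropped.  Default dose
grid in the study configurations is 3 mm; the test fixtures use 4–6 mm to
keep runtimes small.

## Inverse planning

Objectives: one-sided quadratic over/underdose, two-sided quadratic
deviation, one-sided mean dose, max/min dose, and DVH objectives via the
ranked-voxel surrogate (violating voxels between the dose level and the
current dose at the allowed volume fraction are penalized).  All gradients
are analytic.  The solver is L-BFGS-B over w ≥ 0 (projected quasi-Newton),
starting from w ≡ 1, stopping when the relative objective change over five
accepted iterations falls below 1e−5 or at 500 iterations.  Purely
quadratic problems are convex; on ≤50-bixel instances the solver matches an
exact nonnegative-least-squares solution to better than 1e−3 in objective.
Hard constraints are high-penalty soft terms with a post-hoc satisfaction
report.  MLC sequencing is out of scope; segment widths are summarized from
connected runs of the optimized fluence maps only.

## Evaluation conventions

D_x% is the (100−x) percentile of structure voxel doses with linear
interpolation; D_{v cm³} interpolates the hottest-voxel cumulative volume.
Integral dose is the sum of voxel doses divided by the number of voxels of
the evaluated volume (i.e. the body mean dose).  "Average radiological
depth" is a package convention: the mean over beams of the radiological
depth from the surface to the PTV centroid along each beam's central ray.
The gamma analysis is global (normalized to the reference maximum, no
low-dose threshold) and asymmetric by nature; for 1-D curves the evaluated
distribution is treated as a continuous piecewise-linear curve and the
minimum generalized distance is computed exactly per segment — the limit of
arbitrarily fine linear up-sampling, verified against a brute-force
fine-grid oracle to 1e−3.  Volume mode searches displacement offsets within
3·DTA on a DTA/5 lattice and is intended for small grids.

## Monte Carlo transport

Analog photon transport with Woodcock (delta) tracking through the voxel
grid.  Cross sections per material (water, ICRU-46 adult soft tissue ρ 1.06,
skeleton-cranium ρ 1.61, skeleton-femur ρ 1.33) are built semi-empirically:
exact Klein-Nishina Compton (free electrons; sampled from a tabulated
inverse CDF of the energy-ratio distribution), photoelectric derived from
bundled water mass-attenuation/energy-absorption reference values and
scaled across materials with Σ w_i Z_i^4.5/A_i, pair production as a small
anchored Z²-scaled term, coherent scattering neglected.  Water energy-
absorption anchors reproduce the standard tables to ≲2%, and the bone/soft
contrast (μ_tr ratio ≈ 1.5 at 100 keV, ≈ 0.95 at 1 MeV) matches the known
photoelectric signature.  Photoelectric and pair interactions are handled
by implicit capture (weight reduction) with Russian roulette below weight
0.05; the photon cutoff is 10 keV.

Scoring is a track-length collision-kerma estimator (energy transferred to
charged particles, deposited along the flight path) over a 1×1 cm² column
of 2 mm depth bins, with batch-based uncertainties.  Electron transport is
replaced by a one-dimensional causal kerma-to-dose convolution
(an immediate-deposition fraction s0 plus a forward exponential of inverse
range β) whose two parameters are calibrated together with the spectrum
against the engine's depth dose — the same philosophy as tuning the
spectrum itself.  Consequences: lateral electron disequilibrium (e.g. the
penumbra of very small fields) and interface electron effects are not
modeled, which is why the small-field cross-check compares central-axis
depth dose only.

The source is a 1 cm diameter disc at SSD 100 cm, radial intensity falling
linearly to zero at 0.5 cm, collimated to the requested square field at the
phantom surface with uniform target sampling.

### Spectrum tuning

The MC response is linear in the spectrum, so mono-energy-group water
tallies (16 groups, ~12 × 10⁶ histories total, Savitzky-Golay smoothed)
form a basis, and nonnegative group scale factors are solved by
uncertainty-weighted NNLS while a derivative-free outer search fits the
buildup kernel.  PDD→spectrum inversion is ill-posed — many spectra
reproduce one depth-dose curve — so the fit is anchored to the initial
physical bremsstrahlung shape (filtered thin-target family with mode
120 keV and mean 500 keV) by Tikhonov regularization whose strength is
chosen by the discrepancy principle: the strongest anchor whose fall-off
fit stays within 1.5 points.  The tuned 2.5 MV spectrum keeps mean energy
≈0.51 MeV and its modal bin at ~120 keV, and the subsequent independent
2×10⁶-history water run agrees with the engine to ≲1.8 points beyond d_max
and ≲2 points in buildup.

### Bone experiments

Paired runs (soft-tissue phantom with and without a 0.5 cm ρ 1.61 cranium
layer at 1.5–2 cm, or a 4×4×4 cm³ ρ 1.33 femur block at 4–8 cm) share the
bone phantom's Woodcock majorant, so the random-number streams stay aligned
until a trajectory actually samples the insert — a common-random-numbers
estimator that makes the *difference* quantities (notably the distal %dd10
change, read from a local linear fit over 9–11 cm) reproducible to ~0.2
points at 2×10⁶ histories.  Dose is scored to the local medium; the in-bone
increment is the mean ratio over tally bins fully inside the insert (the
peak ratio is also reported), and results are flagged when the compared
bins exceed 2% statistical uncertainty.

### Known limitation: in-bone dose under the kerma approximation

With this transport model the distal perturbations come out at ≈3 points of
%dd10 for the femur block and ≈0.5–1.5 for the cranium layer, but the
*in-bone* dose increments are small (≈+1–3% cranium, ≈0% femur).  That is a
physics consequence, not a statistics one: per gram, bone has *fewer*
electrons than soft tissue (Compton ratio ≈0.95), so a net in-bone increase
must come from photoelectric absorption of low-energy photons, and for any
spectrum with mode ≈120 keV and mean ≈500 keV the sub-150 keV photons carry
only a few percent of the local dose at these depths.  Reported in-bone
increments of order +10% would require roughly a fifth of the local dose in
the sub-150 keV band — i.e. a far softer spectrum than the beam's published
characteristics — or physics outside a photon-kerma model.  The package
reports what its model computes; treat the in-bone numbers as a
kerma-approximation lower bound rather than a prediction of full
coupled-transport results.

## Problem sizes and reproducibility

Default study conditions: 2 mm PDD grids to 30 cm, fields 4–40 cm, 2×10⁶
histories per MC run with 10 batches, 12×10⁶ histories for the tuning
basis, planning phantoms at 4–6 mm voxels with 5 beams of 1 cm bixels in
the test fixtures (3 mm grids and 3–5 mm bixels remain available through
the configuration).  All stochastic stages take explicit seeds and are
bit-reproducible for a fixed seed; the deterministic stages are
seed-independent.
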