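# Methods

This note documents the models, numerical choices and limitations behind
`spectquant`. The package is a simulation-backed implementation of the
standard commissioning workflow for quantitative Lu-177 SPECT: calibrate a
camera with a uniform phantom, optimise OSEM reconstruction parameters on a
NEMA IEC sphere phantom, verify recovery on organ-sized volumes, and
characterise the sensitivity of the metrics to ROI delineation.

## Phantom ground truth

Phantoms are described analytically (background shape, inserts, fill
concentrations) and voxelized by a **voxel-center-inside** test with no
partial-volume antialiasing. This is a deliberate choice: it reproduces the
class of volume mismatch that anatomical (CT-based) delineation of small
spheres exhibits in practice — the 10 mm NEMA sphere voxelized at
2.46 × 2.46 × 2.5 mm can disagree with its analytic volume
(π/6)d³ ≈ 0.52 mL by tens of percent, while spheres ≥ 17 mm stay within
~10%. `mask_volume_discrepancy` quantifies this and reports are expected to
carry it alongside the concentrations, never silently correct for it.

Fill values default to the published phantom session: Ph1 at
122.1 kBq/mL; Ph2 background 783 MBq/9658 mL ≈ 81.1 kBq/mL with spheres at
the 580 kBq/mL stock (≈7:1); Ph3 vials at 129 MBq/130 mL and
521 MBq/535 mL in cold water. Note the stated Ph1 activity and volume
(814 MBq, 6805 mL) imply ≈119.6 kBq/mL rather than 122.1; the exact fill
volume per timepoint is ambiguous, so the simulator parameterizes the
*concentration* directly and does not attempt to resolve the discrepancy.
Decay uses the Lu-177 half-life 6.647 d = 159.528 h; back-decay is refused
because the study design only walks forward along the series.

Geometric choices where the protocol leaves freedom: the NEMA IEC body is
modeled as an elliptical cylinder (semi-axes 147 × 112 mm, height 180 mm,
≈9.6 L) without the cold lung insert, which none of the metrics use; the
six sphere centers sit on a 114.4 mm circle in one transverse plane
(standard NEMA layout); Ph1 is a 216 × 186 mm cylinder (≈6.81 L); the Ph3
vials are cylinders of the stated volumes with height = diameter.
μ(water, 113 keV) defaults to 0.0152 /mm (narrow-beam) and is configurable.

## Projector

The camera is approximated as **2D parallel-beam per transverse slice**,
views uniformly spaced over 360° and ordered as interleaved orbits. The
actual hardware (a ring of swivelling collimated CZT columns) is not
modeled; the quantification mathematics downstream is geometry-agnostic,
and parallel-beam keeps the adjoint exact and desk-fast.

Per view the operator is an explicit sparse matrix: each in-plane voxel
center is splatted onto the detector-bin grid with linear interpolation,
multiplied by a per-voxel attenuation factor `exp(−∫μ dl)` accumulated
along the exit ray (computed by rotating μ so rays align with a grid axis,
cumulative-summing with half weight on the emitting voxel, rotating back),
then blurred by a stationary Gaussian PSF in the detector plane. Because
the adjoint applies the *same* weights, attenuation factors and (symmetric)
blur, the dot-product identity ⟨Ax, y⟩ = ⟨x, Aᵀy⟩ holds to floating-point
round-off — the test suite asserts ≤ 1e−6 relative for every configuration.
Attenuation factors are cached per view in float32 to bound memory
(~100 MB at the reduced profile, ~1 GB at full scale).

**Count scaling.** Expected counts are
`sensitivity × dwell × activity-in-FOV`, with sensitivity in counts/s per
kBq (default 0.025 cps/kBq = 25 cps/MBq). This makes count levels invariant
to the voxel grid. The default puts a Ph2-like acquisition at ≈8 kcps in
the photopeak window, inside the 3.1–13.0 kcps range phantom acquisitions
of this kind occupy; that placement is a soft sanity target of the
simulator design, not a measured detector efficiency.

**PSF.** A single stationary Gaussian, σ = 2.0 mm (FWHM ≈ 4.7 mm). Ring
CZT cameras with registered collimators and geometry modelling inside the
vendor reconstruction have residual tomographic resolution of roughly this
order; since *all* reconstruction variants studied here include geometry
modelling, the simulator blur represents the residual (post-modelling)
response rather than the raw collimator response.

**Window cross-talk** is emulated, not transported. A wide Gaussian blur
(default σ = 25 mm) of the primary, scaled by a downscatter fraction
f_ds = 0.3 and an in-window scatter fraction f_s = 0.1, is added to the
photopeak; the upper flanking window carries `flank_gain_ds × f_ds`-scaled
blur (the 208 keV downscatter carrier) and the lower window the scatter
share. With the default gains of 2.0 the TEW weights (½, ½) recover the
injected contamination **exactly in expectation**, so the correction's
residual error on simulated data is noise, not model bias. All of this is
config-exposed and should be read as artifact plumbing: real contamination
has energy- and depth-dependent structure this one-kernel model does not.
Which flanking window dominates at 113 keV is itself a modelling choice
(here: the upper), flagged for sensitivity analysis.

Poisson sampling uses one child RNG stream per energy window derived from a
single seed, so adding or removing a window never perturbs the other draws.

## Reconstruction

Standard OSEM with the multiplicative update
`x ← x/(AᵀS 1) · AᵀS (y_S / (A_S x + ŝ_S))`, subset S = every n-th view
(maximally interleaved, fixed order), initial estimate uniform 1 on the
attenuating support, zero-sensitivity voxels masked out, fixed update count
(no convergence tolerance — matching the sweep design where *updates* is
the independent variable). With one subset this is MLEM, and the Poisson
log-likelihood `Σ y log ŷ − ŷ` is non-decreasing on noise-free data
(oracle-checked).

**Scatter placement.** The window estimate
`ŝ = (k₁ − k₂k₃)·C_ds + k₂·C_s` (defaults ½C_ds + ½C_s) enters by default
as an additive term in the forward model, the statistically consistent
placement for a Poisson model; `scatter_mode="subtract"` instead
reconstructs the zero-clamped `C_prim = max(C_total − ŝ, 0)`, the literal
pre-subtraction reading. Both modes coincide on clean data (tested); the
additive mode is the default because pre-subtraction biases low-count bins.

**Penalized likelihood.** The vendor's regularizer has unpublished
semantics (including a "freq" parameter), so the package implements a
generic one-step-late quadratic penalty in *relative* form: the gradient
`x − mean(N₆(x))` is normalized by the voxel's own value, and the
denominator multiplier `1 + β·pen` is clamped to [0.5, 2] to keep the
multiplicative update stable. β is therefore dimensionless; β = 1 (the
default for parameter set 2) plateaus background noise at roughly a third
of the unregularized level at high update counts while leaving mean
recovery essentially unchanged — the qualitative behavior that motivates
PL in this context. An earlier variant normalizing by the global mean
over-penalized hot regions and was rejected.

**Post-filters.** Generic Gaussian (mm-parameterized) and 3³ median
filters stand in for the vendor's visualisation-chain convolution and
median filters; the vendor kernels' parameters ("pr", "freq") have no
published meaning and are not guessed.

**Parameter sets.** Set 1 = scatter correction; set 2 = scatter + PL
(β = 1); set 3 = scatter + PSF; set 4 = PSF only. Attenuation correction is
always on. Updates factorize as iterations × subsets with subsets = 8 by
default; the update grid defaults to {32, 64, 96, 128, 160, 256, 384}
(the studied range is 32–384; the intermediate grid is a package choice).

## Quantification

* CF = mean(recon over phantom contour)/injected concentration; a CF is
  computed per reconstruction-parameter set, and calibrated volumes are
  recon/CF. In this simulator the forward and reconstruction models share
  count units, so CF ≈ 1 and the calibration series is a consistency check;
  on a real camera CF absorbs the detector efficiency.
* ARC and CRC use concentrations (not activities) precisely because the
  delineated volumes carry the voxelization mismatch described above.
* Background for CRC/background-RMS: 48 spheres of the same diameter as
  the hot sphere, 12 per cranio-caudal quarter of the phantom, placed by
  seeded rejection sampling with ≥10 mm clearance from the phantom wall and
  insert surfaces, mutually non-overlapping. Placement is a *study-design*
  constant (fixed seed), independent of acquisition noise. Sphere RMS is
  the voxel SD/mean inside a sphere ROI; background RMS is the SD/mean
  across the 48 background-sphere means.
* All SDs are sample (n−1) SDs; the population convention would change the
  printed CoVs in the second decimal at these n. Reported percentages are
  conventionally rounded to 1 decimal, ARCs to 2.
* Delineation: M1 = anatomical (truth) contours; M2 = M1 eroded by a
  metric margin (default one in-plane pixel, 2.46 mm; erosion is
  EDT-based so margins are in mm on anisotropic grids; annihilated masks
  are returned empty with a warning); M3 = threshold at
  ½(max-in-region + background mean), restricted to the connected
  component containing the max, searched in the truth contour dilated by
  5 mm. M1 and M2 share their maximum whenever erosion retains the argmax
  voxel, which the suite asserts.

## Problem sizes and profiles

The default **desk profile** uses a 72 × 72 × 40 grid at
4.92 × 4.92 × 5.0 mm (the acquisition pixel size doubled) and
2 orbits × 60 = 120 views, chosen so that a complete study — calibration
series, sphere sweep, vials — runs in minutes on one CPU; the **full
profile** (256² × 2.46 mm, 240 views) is available behind a flag. Subset
counts must divide the view count, which is why the reduced profile keeps
120 views rather than 60 (8 ∤ 60). `scripts/acceptance.py` and the test
suite run entirely at the desk scale.

## What passing tests do and do not show

The simulator's noise-free, contamination-free arm makes the forward and
reconstruction models *identical*, so recovery failures there indicate
implementation defects, not physics. The contaminated noisy arm shows the
expected *directions* — scatter correction shrinks |ARC−1|, noise grows
with updates, PL suppresses it, mean-based ARCs fall with sphere size —
but the magnitudes depend on the emulated contamination model and the
reduced grid, and are not calibrated against any physical camera. In
particular, detector-specific quantities (a real CF of 0.176, absolute
RMS percentages, max-based ARCs under real noise texture) cannot be
reproduced by construction. No partial-volume correction is applied
anywhere; for spheres below organ size the mean-based ARCs are expected to
sit well below 1.

## Known limitations

No Monte-Carlo photon transport, septal penetration, energy-resolution or
depth-dependent collimator response; no CT chain (the μ-map is the truth
geometry, so "anatomical" contours are exact); no patient workflow or
absorbed-dose computation. The M3 threshold method is noise-sensitive by
design (it keys off a single maximum voxel); at the desk profile's noise
levels it can collapse to a few hot voxels for small spheres, which is a
faithful property of the method rather than a defect of the implementation.
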