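# spectquant

Quantitative SPECT for Lu-177 radiopharmaceutical-therapy monitoring:
a simulation-backed pipeline for camera calibration, OSEM reconstruction
with triple-energy-window (TEW) scatter correction, and NEMA-style
recovery-coefficient analysis.

## What problem this addresses

Dosimetry after Lu-177 therapy (e.g. ¹⁷⁷Lu-PSMA) needs absolute activity
concentrations from SPECT images. Commissioning that capability on a camera
means answering, with phantoms of known fill: what calibration factor (CF)
converts reconstructed voxel values to kBq/mL, how stable it is over a decay
series; which reconstruction options (scatter correction, PSF modelling,
penalized likelihood, number of OSEM updates) best trade off recovery
against noise; and how strongly the answers depend on how regions of
interest are delineated. `spectquant` implements that whole methodology as
reusable, tested code, driven by a synthetic phantom/projection simulator so
every stage can be exercised without access to a physical camera.

## The model in brief

* **Phantoms** — a uniform hot cylinder (Ph1, calibration), a NEMA IEC body
  phantom with six hot spheres of 37–10 mm diameter at a 7:1
  sphere:background fill (Ph2), and a body phantom with two organ-sized hot
  vials of 130 and 535 mL in cold water (Ph3). Ground truth is voxelized by
  a voxel-center-inside test; activity decays physically with the Lu-177
  half-life (6.647 d).
* **Acquisition** — 2D parallel-beam views uniformly covering 360°
  (4 orbits × 60 projections × 3.75 s = 900 s at full scale), attenuation
  along the exit path (`exp(−∫μ dl)`, water μ = 0.0152 /mm at 113 keV), a
  stationary Gaussian detector PSF, and Poisson counts in three energy
  windows: the 113 keV photopeak [101.6; 124.2] keV and two 22.6 keV-wide
  flanking scatter windows. Downscatter from the 208 keV line and in-window
  scatter are emulated as a wide blur of the primary with configurable
  fractions.
* **Reconstruction** — OSEM (iterations × subsets = updates) with
  attenuation in the system matrix; scatter enters through the weighted
  window estimate `C_prim = C_total − (k₁ − k₂k₃)·C_ds − k₂·C_s`
  (k₁ = k₂ = 0.5, k₃ = 0, i.e. TEW `ŝ = ½C_ds + ½C_s`), by default as an
  additive forward-model term; optional PSF modelling and a one-step-late
  penalized-likelihood variant (strength β).
* **Quantification** — `CF = C_est/C_inj` on the uniform phantom;
  `ARC = C*_S/C_S` per sphere (mean- or max-based);
  `CRC = (C*_S/C*_B − 1)/(A_S/A_B − 1)` with the background estimate from
  48 background spheres (12 per cranio-caudal section);
  `RMS(%) = 100·SD/mean`. ROI delineation by anatomical contours (M1),
  eroded contours (M2), or an image threshold at
  `½·(AC_max(sphere) + AC_mean(background))` (M3).

## Worked example

```python
from dataclasses import replace
import spectquant as sq
from spectquant import quant
from spectquant.experiments import (
    desk_profile, simulate_acquisition, recon_params_for_set)
from spectquant.phantoms import build_phantom, hot_vials_phantom, \
    uniform_cylinder_phantom
from spectquant.recon import osem

cfg = replace(desk_profile(noise=False),
              scatter=sq.ScatterEmulation(f_ds=0.0, f_s=0.0))
params = recon_params_for_set(1, updates=96, n_views=cfg.geometry.n_views)

# calibration factor from the uniform cylinder (122.1 kBq/mL fill)
ph1 = build_phantom(uniform_cylinder_phantom(), cfg.grid)
rec1 = osem(simulate_acquisition(ph1, cfg, seed=2), ph1.mu, cfg.grid,
            params, psf_model=cfg.psf)
cf = quant.compute_cf(rec1.values, ph1.body_mask, 122.1)

# organ-sized hot vials, calibrated recovery
ph3 = build_phantom(hot_vials_phantom(), cfg.grid)
rec3 = osem(simulate_acquisition(ph3, cfg, seed=1), ph3.mu, cfg.grid,
            params, psf_model=cfg.psf)
cal = rec3.values / cf
for v in ("vial1", "vial2"):
    arc = quant.compute_arc(cal, ph3.truth_masks[v], ph3.truth_conc[v])
    print(v, round(arc, 3))
```

Output:

```
vial1 0.97
vial2 0.982
```

The CF is ≈0.998 (the simulator and reconstruction share count units, so
calibration is a near-unity consistency check rather than a detector
efficiency), and both organ-sized volumes recover ≥0.9 of the true
concentration at 96 updates (12 iterations × 8 subsets) — the regime in
which mean absorbed-dose estimates in organ-sized regions are considered
reliable; smaller spheres recover progressively less due to partial-volume
effects.

A command-line interface mirrors the study stages:

```bash
spectquant --outdir out --seed 3 simulate --phantom ph2
spectquant --outdir out --seed 3 reconstruct --phantom ph2 --set 1
spectquant --outdir out --seed 3 sweep --sets 1,4 --updates 32,96,160
spectquant --outdir out --seed 3 calibrate --no-noise
spectquant --outdir out --seed 3 compare-segmentation
spectquant accept
```

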