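"""Quantification metrics: calibration factor, ARC, CRC, RMS and ROIs.

Conventions follow the NEMA-style sphere analysis used in Lu-177
quantification studies:

* **CF** — calibration factor, mean reconstructed value inside a uniform
  phantom divided by the injected concentration; dividing a reconstruction
  by its CF yields kBq/mL.
* **ARC** — activity-concentration recovery coefficient, the mean (or max)
  calibrated concentration in a region over the true concentration.
* **CRC** — contrast recovery coefficient,
  ``((C_S*/C_B*) − 1) / (A_S/A_B − 1)``, where the background estimate
  C_B* averages 48 background spheres of the same size as the hot sphere
  (12 per cranio-caudal section, 4 sections).
* **RMS / CoV** — ``100 × SD / mean``, with the *sample* (n−1) standard
  deviation throughout.

Three ROI-delineation methods are provided: M1 uses the anatomical (truth /
CT-surrogate) contours; M2 erodes them by a margin; M3 thresholds the
reconstructed image at half-way between the region maximum and the
background mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .phantoms import GridSpec

__all__ = [
    "CalibrationResult",
    "compute_cf",
    "cf_stability",
    "cov_percent",
    "segment_m1",
    "segment_m2",
    "segment_m3",
    "sample_background_spheres",
    "compute_arc",
    "compute_crc",
    "compute_rms",
    "roi_mean",
]


@dataclass(frozen=True)
class CalibrationResult:
    """Per-timepoint calibration factors and their stability."""

    cfs: tuple[float, ...]
    mean: float
    sd: float
    cov_pct: float


def roi_mean(volume: np.ndarray, mask: np.ndarray) -> float:
    if not mask.any():
        raise ValueError("empty ROI mask")
    return float(volume[mask].mean())


def compute_cf(
    volume: np.ndarray, phantom_mask: np.ndarray, injected_kbq_ml: float
) -> float:
    """CF = mean reconstructed value over the phantom / injected concentration."""
    if injected_kbq_ml <= 0:
        raise ValueError("injected concentration must be positive")
    return roi_mean(volume, phantom_mask) / injected_kbq_ml


def cov_percent(mean: float, sd: float) -> float:
    """Coefficient of variation, 100·SD/mean."""
    if mean == 0:
        raise ValueError("CoV undefined for zero mean")
    return 100.0 * sd / mean


def cf_stability(cfs: Sequence[float]) -> CalibrationResult:
    """Mean, sample SD and CoV% of a calibration-factor series."""
    cfs = tuple(float(c) for c in cfs)
    if len(cfs) < 2:
        raise ValueError("need at least two calibration factors")
    mean = float(np.mean(cfs))
    sd = float(np.std(cfs, ddof=1))
    return CalibrationResult(cfs=cfs, mean=mean, sd=sd,
                             cov_pct=cov_percent(mean, sd))


# ---------------------------------------------------------------------------
# ROI delineation
# ---------------------------------------------------------------------------


def segment_m1(truth_masks: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    """M1: anatomical (CT-surrogate) contours, used as-is."""
    return {name: np.asarray(m, dtype=bool).copy() for name, m in truth_masks.items()}


def segment_m2(
    masks: Mapping[str, np.ndarray],
    margin_mm: float,
    grid: GridSpec,
) -> dict[str, np.ndarray]:
    """M2: contours eroded by ``margin_mm`` (metric ball element).

    Implemented with a Euclidean distance transform so the margin is in mm
    even on anisotropic grids: a voxel survives if its distance to the mask
    exterior exceeds the margin. A margin of 0 returns M1 unchanged; masks
    annihilated by the erosion are returned empty with a warning.
    """
    if margin_mm < 0:
        raise ValueError("margin must be >= 0")
    out: dict[str, np.ndarray] = {}
    for name, mask in masks.items():
        mask = np.asarray(mask, dtype=bool)
        if margin_mm == 0 or not mask.any():
            out[name] = mask.copy()
            continue
        dist = ndimage.distance_transform_edt(mask, sampling=grid.spacing)
        eroded = dist > margin_mm
        if not eroded.any():
            warnings.warn(
                f"M2 erosion by {margin_mm} mm annihilated mask {name!r}",
                stacklevel=2,
            )
        out[name] = eroded
    return out


def segment_m3(
    volume: np.ndarray,
    search_region: np.ndarray,
    bg_mean_kbq_ml: float,
) -> np.ndarray:
    """M3: image-based threshold at ½·(max in region + background mean).

    The mask keeps voxels at or above the threshold, restricted to the
    connected component containing the region maximum.
    """
    search_region = np.asarray(search_region, dtype=bool)
    if not search_region.any():
        raise ValueError("empty search region")
    vals = np.where(search_region, volume, -np.inf)
    if np.all(volume[search_region] == 0):
        raise ValueError("search region is identically zero")
    ac_max = float(vals.max())
    thresh = 0.5 * (ac_max + bg_mean_kbq_ml)
    candidate = (volume >= thresh) & search_region
    labels, _ = ndimage.label(candidate)
    argmax = np.unravel_index(int(np.argmax(vals)), volume.shape)
    return labels == labels[argmax]


def sample_background_spheres(
    diameter_mm: float,
    bg_mask: np.ndarray,
    grid: GridSpec,
    n: int = 48,
    sections: int = 4,
    seed: int = 0,
    clearance_mm: float = 10.0,
    exclude_masks: Sequence[np.ndarray] = (),
    max_attempts_per_section: int = 20000,
) -> list[np.ndarray]:
    """Place ``n`` non-overlapping background spheres, ``n/sections`` per
    cranio-caudal section, fully inside the background with clearance from
    the phantom wall and from the excluded (insert) regions.

    Placement is rejection sampling with a seeded RNG, so results are
    deterministic per seed. Raises a RuntimeError naming the section when a
    section cannot be filled within the attempt budget.
    """
    if n % sections != 0:
        raise ValueError("n must be divisible by the number of sections")
    per_section = n // sections
    bg_mask = np.asarray(bg_mask, dtype=bool)
    if not bg_mask.any():
        raise ValueError("empty background mask")
    radius = diameter_mm / 2.0

    allowed = bg_mask.copy()
    for m in exclude_masks:
        allowed &= ~np.asarray(m, dtype=bool)
    # distance from every allowed voxel to the nearest forbidden voxel
    dist = ndimage.distance_transform_edt(allowed, sampling=grid.spacing)
    need = radius + clearance_mm

    zs = grid.axis_coords(2)[np.any(bg_mask, axis=(0, 1))]
    z_lo, z_hi = float(zs.min()), float(zs.max())
    edges = np.linspace(z_lo, z_hi, sections + 1)

    ii, jj, kk = np.nonzero(dist >= need)
    if ii.size == 0:
        raise RuntimeError("no voxel admits a sphere of this size with clearance")
    cand_z = grid.axis_coords(2)[kk]

    rng = np.random.default_rng(seed)
    xs = grid.axis_coords(0)
    ys = grid.axis_coords(1)
    centers: list[np.ndarray] = []
    X, Y, Z = grid.meshgrid()
    masks: list[np.ndarray] = []
    for s in range(sections):
        lo, hi = edges[s], edges[s + 1]
        in_sec = (cand_z >= lo) & (cand_z <= hi)
        pool = np.nonzero(in_sec)[0]
        placed = 0
        attempts = 0
        while placed < per_section:
            attempts += 1
            if attempts > max_attempts_per_section or pool.size == 0:
                raise RuntimeError(
                    f"could not place {per_section} background spheres in "
                    f"section {s + 1} (diameter {diameter_mm} mm)"
                )
            pick = pool[rng.integers(pool.size)]
            c = np.array([xs[ii[pick]], ys[jj[pick]], cand_z[pick]])
            if any(np.linalg.norm(c - p) < diameter_mm for p in centers):
                continue
            centers.append(c)
            m = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= radius**2
            masks.append(m)
            placed += 1
    return masks


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def compute_arc(
    volume: np.ndarray,
    mask: np.ndarray,
    true_kbq_ml: float,
    statistic: str = "mean",
) -> float:
    """ARC = statistic(calibrated volume over mask) / true concentration."""
    if true_kbq_ml <= 0:
        raise ValueError("true concentration must be positive")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    if statistic == "mean":
        est = float(volume[mask].mean())
    elif statistic == "max":
        est = float(volume[mask].max())
    else:
        raise ValueError("statistic must be 'mean' or 'max'")
    return est / true_kbq_ml


def compute_crc(
    volume: np.ndarray,
    sphere_mask: np.ndarray,
    bg_rois: Sequence[np.ndarray],
    ratio: float,
) -> float:
    """CRC = ((C_S*/C_B*) − 1) / (ratio − 1).

    C_B* is the mean over the background-sphere ROI means. Invariant under
    global rescaling of the volume (any calibration factor cancels).
    """
    if ratio == 1:
        raise ValueError("contrast undefined for a 1:1 ratio")
    if not len(bg_rois):
        raise ValueError("need background ROIs")
    c_s = roi_mean(volume, sphere_mask)
    c_b = float(np.mean([roi_mean(volume, m) for m in bg_rois]))
    return (c_s / c_b - 1.0) / (ratio - 1.0)


def compute_rms(values: Sequence[float] | np.ndarray) -> float:
    """RMS(%) = 100 × sample SD / mean of the values."""
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 2:
        raise ValueError("need at least two values")
    mean = float(values.mean())
    if mean == 0:
        raise ValueError("RMS undefined for zero mean")
    return 100.0 * float(values.std(ddof=1)) / mean
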