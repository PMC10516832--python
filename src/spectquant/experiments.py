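"""Study orchestration: update sweeps, calibration series, ROI comparison.

Reproduces the structure of a quantitative-SPECT commissioning study:

* an *update sweep* over four reconstruction parameter sets
  (1: scatter correction; 2: scatter + penalized likelihood;
  3: scatter + PSF; 4: PSF only) for update counts between 32 and 384,
  reporting per-sphere ARC, CRC and RMS;
* a *calibration series* over the decay timepoints of the uniform
  phantom, reporting per-timepoint calibration factors and their CoV;
* a *segmentation comparison* of the M1/M2/M3 delineation methods on the
  NEMA sphere phantom (mean- and max-based ARCs);
* an *acceptance report* of closed-form protocol arithmetic
  (acquisition duration, window widths, update factorization, decay,
  fill ratio, volume discrepancies, CoV values).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import phantoms, quant
from .phantoms import (
    ACQUISITION_TIMEPOINTS_H,
    GridSpec,
    PhantomRealization,
    PhantomSpec,
    build_phantom,
    decay_concentration,
)
from .projector import (
    AcquisitionGeometry,
    ProjectionSet,
    PSFModel,
    ScatterEmulation,
    SystemModel,
    emulate_window_counts,
    lu177_windows,
    sample_poisson,
)
from .recon import ReconParams, ReconVolume, ScatterParams, osem

__all__ = [
    "SimulationConfig",
    "desk_profile",
    "full_profile",
    "PARAM_SETS",
    "recon_params_for_set",
    "factorize_updates",
    "simulate_acquisition",
    "reconstruct",
    "run_calibration_series",
    "run_update_sweep",
    "run_segmentation_comparison",
    "acceptance_report",
]

DEFAULT_UPDATE_GRID = (32, 64, 96, 128, 160, 256, 384)

#: Additional-parameter sets of the optimisation study.
PARAM_SETS: dict[int, dict] = {
    1: {"scatter_correction": True, "psf": False, "beta": 0.0},
    2: {"scatter_correction": True, "psf": False, "beta": 1.0},
    3: {"scatter_correction": True, "psf": True, "beta": 0.0},
    4: {"scatter_correction": False, "psf": True, "beta": 0.0},
}


@dataclass(frozen=True)
class SimulationConfig:
    """Simulator knobs shared by all studies."""

    grid: GridSpec
    geometry: AcquisitionGeometry
    psf: PSFModel = PSFModel(sigma_mm=2.0)
    scatter: ScatterEmulation = ScatterEmulation()
    sensitivity_cps_per_kbq: float = 2.5e-2
    noise: bool = True


def desk_profile(noise: bool = True) -> SimulationConfig:
    """Reduced grid and orbit count for desk-scale runs.

    ~5 mm voxels over a 354×354×200 mm field and 2 orbits × 60 views
    (subsets of 8 require the view count to be divisible by 8).
    """
    return SimulationConfig(
        grid=GridSpec(shape=(72, 72, 40), spacing=(4.92, 4.92, 5.0)),
        geometry=AcquisitionGeometry(n_orbits=2, views_per_orbit=60),
        noise=noise,
    )


def full_profile(noise: bool = True) -> SimulationConfig:
    """Full acquisition profile: 4 orbits × 60 views, 2.46 mm pixels."""
    return SimulationConfig(
        grid=GridSpec(shape=(256, 256, 128), spacing=(2.46, 2.46, 2.5)),
        geometry=AcquisitionGeometry(n_orbits=4, views_per_orbit=60),
        noise=noise,
    )


def factorize_updates(
    updates: int, n_views: int, subsets: int = 8
) -> tuple[int, int]:
    """Split an update count into (iterations, subsets).

    ``subsets`` must divide both the update count and the view count;
    otherwise the error lists the valid subset choices.
    """
    if updates % subsets == 0 and n_views % subsets == 0:
        return updates // subsets, subsets
    valid = sorted(
        s for s in range(1, min(updates, n_views) + 1)
        if updates % s == 0 and n_views % s == 0
    )
    raise ValueError(
        f"cannot use {subsets} subsets for {updates} updates with "
        f"{n_views} views; valid subset counts: {valid}"
    )


def recon_params_for_set(
    set_id: int, updates: int = 96, n_views: int = 120, subsets: int = 8, **overrides
) -> ReconParams:
    """Expand a parameter-set id (1–4) into full reconstruction params."""
    if set_id not in PARAM_SETS:
        raise ValueError(f"unknown parameter set {set_id}; choose from 1-4")
    iterations, subsets = factorize_updates(updates, n_views, subsets)
    kwargs = dict(PARAM_SETS[set_id])
    kwargs.update(overrides)
    return ReconParams(iterations=iterations, subsets=subsets, **kwargs)


# ---------------------------------------------------------------------------
# Simulation / reconstruction drivers
# ---------------------------------------------------------------------------


def simulate_acquisition(
    realization: PhantomRealization,
    cfg: SimulationConfig,
    seed: int | None = 0,
    model: SystemModel | None = None,
) -> ProjectionSet:
    """Forward-simulate the three-window acquisition of a phantom."""
    if model is None:
        model = SystemModel(
            cfg.grid, cfg.geometry, mu=realization.mu, psf=cfg.psf,
            sensitivity_cps_per_kbq=cfg.sensitivity_cps_per_kbq,
        )
    primary = model.forward(realization.activity)
    expected = emulate_window_counts(primary, cfg.scatter, grid=cfg.grid)
    return sample_poisson(
        expected, cfg.geometry, cfg.sensitivity_cps_per_kbq,
        seed=seed, windows=lu177_windows(), noise=cfg.noise,
    )


def reconstruct(
    proj: ProjectionSet,
    realization: PhantomRealization,
    cfg: SimulationConfig,
    params: ReconParams,
    checkpoints=None,
):
    """OSEM-reconstruct a simulated acquisition (attenuation always on)."""
    return osem(
        proj, realization.mu, cfg.grid, params,
        psf_model=cfg.psf, checkpoints=checkpoints,
    )


def _system_model(realization: PhantomRealization, cfg: SimulationConfig) -> SystemModel:
    return SystemModel(
        cfg.grid, cfg.geometry, mu=realization.mu, psf=cfg.psf,
        sensitivity_cps_per_kbq=cfg.sensitivity_cps_per_kbq,
    )


# ---------------------------------------------------------------------------
# Studies
# ---------------------------------------------------------------------------


def run_calibration_series(
    cfg: SimulationConfig,
    timepoints_h=ACQUISITION_TIMEPOINTS_H["Ph1"],
    c0_kbq_ml: float = 122.1,
    updates: int = 96,
    set_id: int = 1,
    seed: int = 0,
) -> quant.CalibrationResult:
    """Simulate the uniform-cylinder decay series and return CF stability.

    The first timepoint carries ``c0_kbq_ml``; later ones are physically
    decayed. A CF is computed per timepoint from the reconstruction and the
    known injected concentration.
    """
    timepoints_h = tuple(timepoints_h)
    if len(timepoints_h) < 2:
        raise ValueError("need at least two timepoints")
    t0 = timepoints_h[0]
    params = recon_params_for_set(set_id, updates, cfg.geometry.n_views)
    cfs = []
    seeds = np.random.SeedSequence(seed).generate_state(len(timepoints_h))
    base = phantoms.uniform_cylinder_phantom(concentration_kbq_ml=c0_kbq_ml)
    real0 = build_phantom(base, cfg.grid)
    model = _system_model(real0, cfg)
    recon_model = SystemModel(
        cfg.grid, cfg.geometry, mu=real0.mu,
        psf=cfg.psf if params.psf else None,
        sensitivity_cps_per_kbq=cfg.sensitivity_cps_per_kbq,
    )
    for t, s in zip(timepoints_h, seeds):
        conc = decay_concentration(c0_kbq_ml, t0, t)
        real = build_phantom(base.with_concentrations(background_kbq_ml=conc), cfg.grid)
        proj = simulate_acquisition(real, cfg, seed=int(s % (2**31)), model=model)
        vol = osem(proj, real.mu, cfg.grid, params,
                   psf_model=cfg.psf, model=recon_model)
        cfs.append(quant.compute_cf(vol.values, real.body_mask, conc))
    return quant.cf_stability(cfs)


def _sphere_metrics(
    calibrated: np.ndarray,
    realization: PhantomRealization,
    bg_rois_by_sphere: dict[str, list[np.ndarray]] | None,
    ratio: float | None,
) -> list[dict]:
    rows = []
    bg_mask = realization.truth_masks["background"]
    for name, conc in realization.truth_conc.items():
        if name == "background":
            continue
        mask = realization.truth_masks[name]
        row = {
            "sphere": name,
            "arc_mean": quant.compute_arc(calibrated, mask, conc, "mean"),
            "arc_max": quant.compute_arc(calibrated, mask, conc, "max"),
            "rms_sphere_pct": quant.compute_rms(calibrated[mask]),
        }
        if bg_rois_by_sphere is not None and ratio is not None:
            rois = bg_rois_by_sphere[name]
            row["crc"] = quant.compute_crc(calibrated, mask, rois, ratio)
            row["rms_background_pct"] = quant.compute_rms(
                [quant.roi_mean(calibrated, m) for m in rois]
            )
        rows.append(row)
    return rows


def background_rois_for_spheres(
    realization: PhantomRealization,
    grid: GridSpec,
    placement_seed: int = 0,
    clearance_mm: float = 10.0,
) -> dict[str, list[np.ndarray]]:
    """48 background spheres (12 per cranio-caudal section) per sphere size.

    Placement is a study-design constant: it depends on the phantom
    geometry and a fixed seed, not on the acquisition noise.
    """
    bg = realization.truth_masks["background"]
    inserts = [
        m for n, m in realization.truth_masks.items() if n != "background"
    ]
    out = {}
    for ins in realization.spec.inserts:
        out[ins.name] = quant.sample_background_spheres(
            ins.diameter_mm, bg, grid, seed=placement_seed,
            clearance_mm=clearance_mm, exclude_masks=inserts,
        )
    return out


def run_update_sweep(
    realization: PhantomRealization,
    cfg: SimulationConfig,
    sets=(1, 2, 3, 4),
    updates_list=DEFAULT_UPDATE_GRID,
    seed: int = 0,
    cf_per_set: dict[int, float] | None = None,
    bg_rois_by_sphere: dict[str, list[np.ndarray]] | None = None,
) -> pd.DataFrame:
    """ARC/CRC/RMS per sphere over parameter sets and update counts.

    Each set is reconstructed once to the maximum update count with
    snapshots at every requested count (a fixed subset schedule makes the
    snapshot after u updates identical to a u-update reconstruction).
    ``cf_per_set`` supplies per-set calibration factors (e.g. from the
    uniform phantom under the same conditions); without it the volumes are
    used uncalibrated (CF = 1).

    Returns a long-form table keyed by (set, updates, sphere, metric).
    """
    updates_list = sorted(set(updates_list))
    n_views = cfg.geometry.n_views
    for u in updates_list:
        factorize_updates(u, n_views)
    proj = simulate_acquisition(realization, cfg, seed=seed)
    try:
        ratio = phantoms.concentration_ratio(realization.spec)
    except ValueError:
        ratio = None

    records = []
    models: dict[bool, SystemModel] = {}
    for set_id in sets:
        params = recon_params_for_set(set_id, max(updates_list), n_views)
        if params.psf not in models:
            models[params.psf] = SystemModel(
                cfg.grid, cfg.geometry, mu=realization.mu,
                psf=cfg.psf if params.psf else None,
                sensitivity_cps_per_kbq=cfg.sensitivity_cps_per_kbq,
            )
        _, snaps = osem(
            proj, realization.mu, cfg.grid, params,
            psf_model=cfg.psf, model=models[params.psf],
            checkpoints=updates_list,
        )
        cf = (cf_per_set or {}).get(set_id, 1.0)
        for u in updates_list:
            calibrated = snaps[u] / cf
            for row in _sphere_metrics(
                calibrated, realization, bg_rois_by_sphere, ratio
            ):
                for metric, value in row.items():
                    if metric == "sphere":
                        continue
                    records.append(
                        {
                            "set": set_id,
                            "updates": u,
                            "sphere": row["sphere"],
                            "metric": metric,
                            "value": value,
                        }
                    )
    df = pd.DataFrame.from_records(records)
    df.attrs["provenance"] = {
        "seed": seed,
        "grid": list(cfg.grid.shape),
        "noise": cfg.noise,
        "scatter_model": vars(cfg.scatter).copy() if hasattr(cfg.scatter, "__dict__")
        else {k: getattr(cfg.scatter, k) for k in ("f_ds", "f_s", "blur_sigma_mm")},
    }
    return df


def run_segmentation_comparison(
    calibrated: np.ndarray,
    realization: PhantomRealization,
    grid: GridSpec,
    m2_margin_mm: float = 2.46,
) -> pd.DataFrame:
    """Mean/max ARC matrix for the M1, M2, M3 delineation methods.

    Rows: method × statistic (6); columns: one per sphere. M3 searches in
    the truth contour dilated by 5 mm and thresholds at half-way between
    the region maximum and the background mean.
    """
    from scipy import ndimage

    sphere_masks = {
        n: m for n, m in realization.truth_masks.items() if n != "background"
    }
    bg_mean = quant.roi_mean(calibrated, realization.truth_masks["background"])
    m1 = quant.segment_m1(sphere_masks)
    m2 = quant.segment_m2(m1, m2_margin_mm, grid)
    m3 = {}
    dilate_vox = tuple(
        max(1, int(round(5.0 / s))) for s in grid.spacing
    )
    for name, mask in m1.items():
        region = ndimage.binary_dilation(
            mask, iterations=max(dilate_vox)
        )
        m3[name] = quant.segment_m3(calibrated, region, bg_mean)

    rows = {}
    for label, masks in (("M1", m1), ("M2", m2), ("M3", m3)):
        for stat in ("mean", "max"):
            vals = {}
            for name, mask in masks.items():
                conc = realization.truth_conc[name]
                if mask.any():
                    vals[name] = quant.compute_arc(calibrated, mask, conc, stat)
                else:
                    vals[name] = np.nan
            rows[f"{label}_{stat}"] = vals
    return pd.DataFrame(rows).T


def plot_sweep(df: pd.DataFrame, path, metric: str = "arc_mean"):
    """Metric-vs-updates curves, one panel per parameter set.

    One line per sphere, mirroring the usual presentation of recovery and
    noise versus the number of OSEM updates.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sel = df[df.metric == metric]
    sets = sorted(sel["set"].unique())
    fig, axes = plt.subplots(
        1, len(sets), figsize=(4 * len(sets), 3.2), sharey=True, squeeze=False
    )
    for ax, set_id in zip(axes[0], sets):
        sub = sel[sel["set"] == set_id]
        for sphere, grp in sub.groupby("sphere"):
            grp = grp.sort_values("updates")
            ax.plot(grp["updates"], grp["value"], marker="o", label=sphere)
        ax.set_title(f"set {set_id}")
        ax.set_xlabel("updates")
    axes[0][0].set_ylabel(metric)
    axes[0][-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


# ---------------------------------------------------------------------------
# Protocol arithmetic report
# ---------------------------------------------------------------------------


def acceptance_report() -> pd.DataFrame:
    """Closed-form protocol arithmetic with expected values.

    Every row is pure arithmetic on the published protocol constants,
    recomputed through the package's own functions.
    """
    wins = lu177_windows()
    ph2 = phantoms.nema_iec_phantom()
    checks = [
        (
            "acquisition_duration_s",
            AcquisitionGeometry(4, 60, 3.75).total_duration_s,
            900.0,
        ),
        ("scatter_window_width_lower_kev", wins["lower"].width_kev, 22.6),
        ("scatter_window_width_upper_kev", wins["upper"].width_kev, 22.6),
        ("updates_12it_8sub", ReconParams(iterations=12, subsets=8).updates, 96),
        (
            "decayed_concentration_kbq_ml",
            round(decay_concentration(122.1, 5.1, 338.6), 1),
            28.7,
        ),
        (
            "ph2_sphere_to_background_ratio",
            round(phantoms.concentration_ratio(ph2)),
            7,
        ),
        (
            "smallest_sphere_volume_discrepancy_pct",
            round(phantoms.mask_volume_discrepancy(0.36, 0.52)),
            31,
        ),
        (
            "large_sphere_volume_discrepancy_pct",
            round(phantoms.mask_volume_discrepancy(6.1, 5.6), 1),
            8.9,
        ),
        ("cf_cov_pct", round(quant.cov_percent(0.176, 0.00444), 1), 2.5),
        ("small_organ_arc_cov_pct", round(quant.cov_percent(0.91, 0.0117), 1), 1.3),
        ("large_organ_arc_cov_pct", round(quant.cov_percent(0.91, 0.0082), 1), 0.9),
    ]
    df = pd.DataFrame(checks, columns=["check", "value", "expected"])
    df["pass"] = np.isclose(
        df["value"].astype(float), df["expected"].astype(float), atol=1e-9
    )
    return df
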