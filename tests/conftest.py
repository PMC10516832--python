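"""Shared fixtures: small deterministic simulation studies.

Heavy reconstructions are session-scoped and shared across tests; they use
a reduced grid (~5 mm voxels, 120 views) so the whole suite runs at desk
scale. Noise-free arms disable window contamination so model-mismatch-free
properties (likelihood monotonicity, recovery) are exact.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

import spectquant as sq
from spectquant import quant
from spectquant.experiments import (
    desk_profile,
    recon_params_for_set,
    simulate_acquisition,
)
from spectquant.phantoms import (
    GridSpec,
    build_phantom,
    hot_vials_phantom,
    nema_iec_phantom,
    uniform_cylinder_phantom,
)
from spectquant.projector import AcquisitionGeometry, PSFModel, ScatterEmulation
from spectquant.recon import osem


@pytest.fixture(scope="session")
def tiny_grid() -> GridSpec:
    return GridSpec((24, 24, 6), (4.0, 4.0, 5.0))


@pytest.fixture(scope="session")
def tiny_geom() -> AcquisitionGeometry:
    return AcquisitionGeometry(n_orbits=1, views_per_orbit=24)


@pytest.fixture(scope="session")
def clean_cfg():
    """Desk-profile config, noise-free, no window contamination."""
    return replace(
        desk_profile(noise=False),
        scatter=ScatterEmulation(f_ds=0.0, f_s=0.0),
    )


@pytest.fixture(scope="session")
def noisy_cfg():
    """Desk-profile config with default contamination and Poisson noise."""
    return desk_profile(noise=True)


@pytest.fixture(scope="session")
def ph1_clean(clean_cfg):
    """Noise-free uniform-cylinder study: realization, recon, CF."""
    real = build_phantom(uniform_cylinder_phantom(), clean_cfg.grid)
    proj = simulate_acquisition(real, clean_cfg, seed=11)
    params = recon_params_for_set(1, 96, clean_cfg.geometry.n_views)
    vol = osem(proj, real.mu, clean_cfg.grid, params, psf_model=clean_cfg.psf)
    cf = quant.compute_cf(vol.values, real.body_mask, 122.1)
    return {"real": real, "vol": vol, "cf": cf}


@pytest.fixture(scope="session")
def ph2_clean(clean_cfg, ph1_clean):
    """Noise-free NEMA-sphere study with update snapshots and calibration."""
    real = build_phantom(nema_iec_phantom(), clean_cfg.grid)
    proj = simulate_acquisition(real, clean_cfg, seed=12)
    params = recon_params_for_set(1, 384, clean_cfg.geometry.n_views)
    _, snaps = osem(
        proj, real.mu, clean_cfg.grid, params,
        psf_model=clean_cfg.psf, checkpoints=[32, 96, 384],
    )
    cf = ph1_clean["cf"]
    return {
        "real": real,
        "snapshots": snaps,
        "cf": cf,
        "calibrated_96": snaps[96] / cf,
    }


@pytest.fixture(scope="session")
def ph3_clean(clean_cfg, ph1_clean):
    """Noise-free hot-vials study (organ-sized volumes), calibrated."""
    real = build_phantom(hot_vials_phantom(), clean_cfg.grid)
    proj = simulate_acquisition(real, clean_cfg, seed=13)
    params = recon_params_for_set(1, 96, clean_cfg.geometry.n_views)
    vol = osem(proj, real.mu, clean_cfg.grid, params, psf_model=clean_cfg.psf)
    return {"real": real, "calibrated": vol.values / ph1_clean["cf"]}


@pytest.fixture(scope="session")
def ph2_noisy(noisy_cfg):
    """Fixed-seed contaminated noisy NEMA study, sets 1 and 4.

    Per-set calibration factors come from the uniform phantom simulated
    under the same (contaminated, noisy) conditions, mirroring the study
    design where every reconstruction set gets its own CF.
    """
    cfg = noisy_cfg
    real2 = build_phantom(nema_iec_phantom(), cfg.grid)
    proj2 = simulate_acquisition(real2, cfg, seed=7)
    real1 = build_phantom(uniform_cylinder_phantom(), cfg.grid)
    proj1 = simulate_acquisition(real1, cfg, seed=8)
    out = {"real": real2, "sets": {}}
    for set_id, checkpoints in ((1, [32, 96, 160, 384]), (4, [96])):
        params = recon_params_for_set(set_id, max(checkpoints), cfg.geometry.n_views)
        _, snaps2 = osem(
            proj2, real2.mu, cfg.grid, params,
            psf_model=cfg.psf, checkpoints=checkpoints,
        )
        _, snaps1 = osem(
            proj1, real1.mu, cfg.grid, params,
            psf_model=cfg.psf, checkpoints=checkpoints,
        )
        cfs = {
            u: quant.compute_cf(snaps1[u], real1.body_mask, 122.1)
            for u in checkpoints
        }
        out["sets"][set_id] = {"snapshots": snaps2, "cfs": cfs}
    return out
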