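"""Scatter estimation, OSEM behavior and post-filters."""

import numpy as np
import pytest

from spectquant.phantoms import GridSpec, build_phantom, uniform_cylinder_phantom
from spectquant.projector import (
    AcquisitionGeometry,
    ProjectionSet,
    ScatterEmulation,
    SystemModel,
    emulate_window_counts,
    lu177_windows,
    sample_poisson,
)
from spectquant.recon import (
    ReconParams,
    ScatterParams,
    apply_postfilter,
    estimate_scatter,
    likelihood,
    osem,
)


def _proj_from_counts(c_total, c_s, c_ds, geom=None):
    geom = geom or AcquisitionGeometry(1, 12)
    shape = (geom.n_views, 8, 2)
    return ProjectionSet(
        counts={
            "photopeak": np.full(shape, float(c_total)),
            "lower": np.full(shape, float(c_s)),
            "upper": np.full(shape, float(c_ds)),
        },
        geometry=geom,
        windows=lu177_windows(),
        sensitivity_cps_per_kbq=0.025,
    )


class TestScatterEstimate:
    @pytest.mark.parametrize(
        "k,s_expected,prim_expected",
        [
            (ScatterParams(), 150.0, 850.0),  # defaults k1=k2=0.5, k3=0
            (ScatterParams(k3=1.0), 50.0, 950.0),  # k1 - k2*k3 = 0
        ],
    )
    def test_weighted_window_arithmetic(self, k, s_expected, prim_expected):
        proj = _proj_from_counts(c_total=1000, c_s=100, c_ds=200)
        s_hat, c_prim = estimate_scatter(proj, k)
        assert np.allclose(s_hat, s_expected)
        assert np.allclose(c_prim, prim_expected)

    def test_no_flank_counts_passthrough(self):
        proj = _proj_from_counts(c_total=1000, c_s=0, c_ds=0)
        s_hat, c_prim = estimate_scatter(proj)
        assert np.all(s_hat == 0)
        assert np.allclose(c_prim, proj.c_total)

    def test_missing_window_rejected(self):
        proj = _proj_from_counts(1000, 100, 200)
        del proj.counts["lower"]
        with pytest.raises(ValueError):
            estimate_scatter(proj)


@pytest.fixture(scope="module")
def small_uniform_study():
    """Noise-free uniform cylinder on a tiny grid, no contamination."""
    grid = GridSpec((32, 32, 4), (6.0, 6.0, 6.0))
    geom = AcquisitionGeometry(1, 30)
    spec = uniform_cylinder_phantom(100.0, diameter_mm=120, height_mm=24)
    real = build_phantom(spec, grid)
    model = SystemModel(grid, geom, mu=real.mu)
    primary = model.forward(real.activity)
    exp = emulate_window_counts(primary, ScatterEmulation(0.0, 0.0), grid=grid)
    proj = sample_poisson(exp, geom, model.sensitivity_cps_per_kbq,
                          seed=None, noise=False)
    return {"grid": grid, "geom": geom, "real": real, "model": model, "proj": proj}


class TestOsem:
    def test_zero_counts_give_zero_volume(self, small_uniform_study):
        s = small_uniform_study
        zero = ProjectionSet(
            counts={k: np.zeros_like(v) for k, v in s["proj"].counts.items()},
            geometry=s["geom"], windows=lu177_windows(),
            sensitivity_cps_per_kbq=0.025,
        )
        vol = osem(zero, s["real"].mu, s["grid"],
                   ReconParams(iterations=1, subsets=1, scatter_correction=False))
        assert np.all(vol.values == 0)

    def test_mlem_likelihood_monotone_noise_free(self, small_uniform_study):
        """Poisson log-likelihood never decreases across MLEM iterations."""
        s = small_uniform_study
        params = ReconParams(iterations=50, subsets=1, scatter_correction=False)
        _, snaps = osem(s["proj"], s["real"].mu, s["grid"], params,
                        checkpoints=list(range(1, 51)))
        lls = [likelihood(s["proj"].c_total, snaps[u], s["model"])
               for u in range(1, 51)]
        diffs = np.diff(lls)
        assert np.all(diffs >= -1e-8 * np.abs(lls[0]))

    def test_uniform_recovery_within_2pct(self, small_uniform_study):
        """≥96 updates recover a noise-free uniform cylinder within 2%."""
        s = small_uniform_study
        params = ReconParams(iterations=16, subsets=6, scatter_correction=False)
        assert params.updates == 96
        vol = osem(s["proj"], s["real"].mu, s["grid"], params)
        mean = vol.values[s["real"].body_mask].mean()
        assert mean == pytest.approx(100.0, rel=0.02)

    def test_nonnegativity_and_truth_is_likelihood_peak(self, small_uniform_study):
        s = small_uniform_study
        params = ReconParams(iterations=4, subsets=6, scatter_correction=False)
        vol = osem(s["proj"], s["real"].mu, s["grid"], params)
        assert np.all(vol.values >= 0)
        ll_truth = likelihood(s["proj"].c_total, s["real"].activity, s["model"])
        rng = np.random.default_rng(0)
        for _ in range(3):
            perturbed = s["real"].activity * rng.uniform(0.7, 1.3)
            assert likelihood(s["proj"].c_total, perturbed, s["model"]) <= ll_truth

    def test_subsets_must_divide_views(self, small_uniform_study):
        s = small_uniform_study
        with pytest.raises(ValueError, match="divide"):
            osem(s["proj"], s["real"].mu, s["grid"],
                 ReconParams(iterations=1, subsets=7, scatter_correction=False))

    def test_scatter_modes_agree_on_clean_data(self, small_uniform_study):
        """With empty flanking windows both scatter modes reduce to MLEM."""
        s = small_uniform_study
        out = {}
        for mode in ("additive", "subtract"):
            params = ReconParams(iterations=4, subsets=6, scatter_mode=mode)
            out[mode] = osem(s["proj"], s["real"].mu, s["grid"], params).values
        assert np.allclose(out["additive"], out["subtract"])

    def test_penalized_lowers_background_noise(self):
        """β>0 lowers voxel RMS at equal updates on fixed-seed noisy data."""
        grid = GridSpec((32, 32, 4), (6.0, 6.0, 6.0))
        geom = AcquisitionGeometry(1, 30)
        real = build_phantom(
            uniform_cylinder_phantom(100.0, diameter_mm=120, height_mm=24), grid
        )
        model = SystemModel(grid, geom, mu=real.mu)
        exp = emulate_window_counts(
            model.forward(real.activity), ScatterEmulation(0.0, 0.0), grid=grid
        )
        proj = sample_poisson(exp, geom, model.sensitivity_cps_per_kbq, seed=21)
        rms = {}
        for beta in (0.0, 1.0):
            params = ReconParams(iterations=16, subsets=6,
                                 scatter_correction=False, beta=beta)
            vol = osem(proj, real.mu, grid, params)
            vals = vol.values[real.body_mask]
            rms[beta] = vals.std(ddof=1) / vals.mean()
        assert rms[1.0] < rms[0.0]


class TestPostFilters:
    def test_median_constant_invariant_and_impulse_removal(self):
        vol = np.full((10, 10, 10), 4.0)
        assert np.array_equal(apply_postfilter(vol, ("median", 3)), vol)
        vol[5, 5, 5] = 100.0
        filtered = apply_postfilter(vol, "median:3")
        assert filtered[5, 5, 5] == 4.0

    def test_gaussian_preserves_interior_mass(self):
        grid = GridSpec((21, 21, 21), (2.0, 2.0, 2.0))
        vol = np.zeros(grid.shape)
        vol[10, 10, 10] = 1.0
        out = apply_postfilter(vol, ("gaussian", 2.0), grid)
        assert out.sum() == pytest.approx(1.0, rel=1e-6)

    def test_unknown_filter_rejected(self):
        with pytest.raises(ValueError):
            apply_postfilter(np.zeros((3, 3, 3)), ("wiener", 1))
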