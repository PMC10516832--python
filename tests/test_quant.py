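"""Calibration factor, delineation methods and NEMA-style metrics."""

import math
import warnings

import numpy as np
import pytest

from spectquant.phantoms import GridSpec, build_phantom, nema_iec_phantom
from spectquant.quant import (
    cf_stability,
    compute_arc,
    compute_cf,
    compute_crc,
    compute_rms,
    cov_percent,
    roi_mean,
    sample_background_spheres,
    segment_m1,
    segment_m2,
    segment_m3,
)

GRID = GridSpec((64, 64, 32), (2.46, 2.46, 2.5))


@pytest.fixture(scope="module")
def sphere_mask():
    """A 37 mm sphere voxelized at the acquisition pixel size."""
    X, Y, Z = GRID.meshgrid()
    return X**2 + Y**2 + Z**2 <= 18.5**2


class TestCalibration:
    def test_cf_identity_and_scaling(self, sphere_mask):
        vol = np.where(sphere_mask, 80.0, 0.0)
        assert compute_cf(vol, sphere_mask, 80.0) == pytest.approx(1.0)
        assert compute_cf(vol * 0.176, sphere_mask, 80.0) == pytest.approx(0.176)

    def test_self_calibration_recovers_injected(self, sphere_mask):
        vol = np.where(sphere_mask, 33.0, 0.0)
        cf = compute_cf(vol, sphere_mask, 80.0)
        assert roi_mean(vol / cf, sphere_mask) == pytest.approx(80.0)

    def test_published_cf_series_cov(self):
        """Mean 0.176, SD 0.00444 give the published 2.5% CoV."""
        assert cov_percent(0.176, 0.00444) == pytest.approx(2.5, abs=0.05)

    def test_cf_stability_identical_values(self):
        res = cf_stability([0.2] * 5)
        assert res.cov_pct == 0.0
        assert res.sd == 0.0

    def test_cf_stability_needs_two(self):
        with pytest.raises(ValueError):
            cf_stability([0.2])


class TestSegmentation:
    def test_m1_is_identity(self, sphere_mask):
        masks = {"s": sphere_mask}
        out = segment_m1(masks)
        assert np.array_equal(out["s"], sphere_mask)
        assert out["s"] is not sphere_mask  # defensive copy

    def test_m2_zero_margin_unchanged(self, sphere_mask):
        out = segment_m2({"s": sphere_mask}, 0.0, GRID)
        assert np.array_equal(out["s"], sphere_mask)

    def test_m2_erosion_shrinks_but_keeps_center(self, sphere_mask):
        out = segment_m2({"s": sphere_mask}, 2.46, GRID)["s"]
        assert 0 < out.sum() < sphere_mask.sum()
        center = tuple(np.array(GRID.shape) // 2)
        assert out[center]
        assert np.all(sphere_mask[out])  # M2 ⊆ M1

    def test_m2_annihilates_small_sphere_with_warning(self):
        X, Y, Z = GRID.meshgrid()
        tiny = X**2 + Y**2 + Z**2 <= 5.0**2  # 10 mm sphere
        with pytest.warns(UserWarning, match="annihilated"):
            out = segment_m2({"tiny": tiny}, 5.0, GRID)
        assert out["tiny"].sum() == 0

    @pytest.mark.parametrize(
        "ac_max,bg_mean,expected",
        [(100.0, 20.0, 60.0), (100.0, 0.0, 50.0)],
    )
    def test_m3_threshold_rule(self, sphere_mask, ac_max, bg_mean, expected):
        vol = np.where(sphere_mask, ac_max, 0.0)
        m3 = segment_m3(vol, sphere_mask, bg_mean)
        assert np.array_equal(m3, sphere_mask)  # uniform sphere ≥ threshold
        # the implied threshold keeps a voxel exactly at it
        vol2 = vol.copy()
        edge = np.argwhere(sphere_mask)[0]
        vol2[tuple(edge)] = expected - 1e-9
        assert not segment_m3(vol2, sphere_mask, bg_mean)[tuple(edge)]

    def test_m3_restricted_to_component_of_max(self):
        vol = np.zeros(GRID.shape)
        vol[10:13, 10:13, 10:13] = 50.0  # satellite blob
        vol[40:45, 40:45, 20:25] = 100.0  # hot blob containing the max
        region = vol > 0
        m3 = segment_m3(vol, region, 0.0)
        assert m3[42, 42, 22]
        assert not m3[11, 11, 11]


@pytest.fixture(scope="module")
def ph2():
    grid = GridSpec((72, 72, 40), (4.92, 4.92, 5.0))
    return build_phantom(nema_iec_phantom(), grid), grid


class TestBackgroundSpheres:

    def test_contract_48_in_4_sections_nonoverlapping(self, ph2):
        real, grid = ph2
        inserts = [m for n, m in real.truth_masks.items() if n != "background"]
        masks = sample_background_spheres(
            28.0, real.truth_masks["background"], grid,
            seed=0, exclude_masks=inserts,
        )
        assert len(masks) == 48
        stack = np.array([m.sum() for m in masks])
        assert np.all(stack > 0)
        union = np.zeros(grid.shape, int)
        for m in masks:
            union += m
        assert union.max() == 1  # mutually disjoint
        assert np.all(real.truth_masks["background"][union.astype(bool)])
        for m in masks:  # stays clear of the hot spheres
            for ins in inserts:
                assert not np.any(m & ins)

    def test_seed_determinism(self, ph2):
        real, grid = ph2
        a = sample_background_spheres(17.0, real.truth_masks["background"], grid, seed=3)
        b = sample_background_spheres(17.0, real.truth_masks["background"], grid, seed=3)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_volumes_near_analytic(self, ph2):
        real, grid = ph2
        masks = sample_background_spheres(
            28.0, real.truth_masks["background"], grid, seed=0
        )
        analytic = math.pi / 6 * 28.0**3 / 1000.0
        vols = np.array([m.sum() for m in masks]) * grid.voxel_volume_ml
        # voxelization scatter at ~5 mm voxels
        assert np.all(np.abs(vols - analytic) / analytic < 0.35)

    def test_infeasible_placement_names_section(self, ph2):
        # 80 mm spheres admit a few placements but never 12 per section
        real, grid = ph2
        with pytest.raises(RuntimeError, match="section"):
            sample_background_spheres(
                80.0, real.truth_masks["background"], grid, seed=0,
                max_attempts_per_section=200,
            )


class TestMetrics:
    def test_arc_scaling(self, sphere_mask):
        vol = np.where(sphere_mask, 40.0, 0.0)
        assert compute_arc(vol, sphere_mask, 40.0) == pytest.approx(1.0)
        assert compute_arc(vol, sphere_mask, 80.0) == pytest.approx(0.5)

    def test_arc_max_geq_mean(self, sphere_mask):
        rng = np.random.default_rng(1)
        vol = rng.random(GRID.shape) * 100
        a_mean = compute_arc(vol, sphere_mask, 50.0, "mean")
        a_max = compute_arc(vol, sphere_mask, 50.0, "max")
        assert a_max >= a_mean

    def test_crc_reference_points(self, sphere_mask):
        bg = ~sphere_mask
        bg_rois = [bg & (np.arange(GRID.shape[2])[None, None, :] == k)
                   for k in (2, 10, 20)]
        vol = np.where(sphere_mask, 70.0, 10.0)
        assert compute_crc(vol, sphere_mask, bg_rois, 7.0) == pytest.approx(1.0)
        vol_flat = np.full(GRID.shape, 10.0)
        assert compute_crc(vol_flat, sphere_mask, bg_rois, 7.0) == pytest.approx(0.0)
        vol_half = np.where(sphere_mask, 40.0, 10.0)  # contrast 4 at ratio 7
        assert compute_crc(vol_half, sphere_mask, bg_rois, 7.0) == pytest.approx(0.5)

    def test_crc_unit_ratio_rejected(self, sphere_mask):
        with pytest.raises(ValueError):
            compute_crc(np.ones(GRID.shape), sphere_mask, [~sphere_mask], 1.0)

    @pytest.mark.parametrize(
        "mean,sd,expected", [(0.91, 0.0117, 1.3), (0.91, 0.0082, 0.9)]
    )
    def test_published_arc_variability(self, mean, sd, expected):
        assert cov_percent(mean, sd) == pytest.approx(expected, abs=0.05)

    def test_rms_constant_is_zero(self):
        assert compute_rms([3.0, 3.0, 3.0]) == 0.0
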