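"""Synthetic phantom: mask geometry, field kernel, recruitment, datasets."""

import numpy as np
import pytest
from scipy import ndimage

from tmsinv.data import preprocess
from tmsinv.phantom import (PhantomConfig, generate_dataset,
                            make_muscle_weight_maps, make_phantom_mask,
                            simulate_efield, simulate_mep)


class TestMask:
    def test_fraction_and_connectivity_full_scale(self):
        mask = make_phantom_mask((64, 64, 64), 0.02, seed=0)
        frac = mask.grid.mean()
        assert 0.015 <= frac <= 0.025
        _, n_comp = ndimage.label(mask.grid)
        assert n_comp == 1

    def test_deterministic_and_fraction_test_scale(self):
        a = make_phantom_mask((16, 16, 16), 0.05, seed=3)
        b = make_phantom_mask((16, 16, 16), 0.05, seed=3)
        np.testing.assert_array_equal(a.grid, b.grid)
        assert 0.0375 <= a.grid.mean() <= 0.0625

    def test_zero_fraction_rejected(self):
        with pytest.raises(ValueError):
            make_phantom_mask((16, 16, 16), 0.0, seed=0)


class TestEField:
    @pytest.fixture(scope="class")
    def setup(self):
        cfg = PhantomConfig.test_scale(seed=2)
        mask = make_phantom_mask(cfg.shape, cfg.mask_fraction, seed=2)
        return cfg, mask

    def _center_coil(self, cfg, mask):
        vs = cfg.voxel_size
        centroid = np.argwhere(mask.grid > 0).mean(axis=0) * vs
        return np.array([centroid[0], centroid[1],
                         centroid[2] + cfg.coil_standoff_mm])

    def test_peak_at_mask_voxel_nearest_coil(self, setup):
        cfg, mask = setup
        coil = self._center_coil(cfg, mask)
        vol, fringe = simulate_efield(coil, 45.0, 140, mask, cfg)
        assert not fringe
        peak = np.unravel_index(np.argmax(vol.grid), vol.grid.shape)
        mask_vox = np.argwhere(mask.grid > 0)
        d = np.linalg.norm(mask_vox * cfg.voxel_size - coil, axis=1)
        np.testing.assert_array_equal(peak, mask_vox[np.argmin(d)])

    def test_intensity_monotone(self, setup):
        cfg, mask = setup
        coil = self._center_coil(cfg, mask)
        v110, _ = simulate_efield(coil, 45.0, 110, mask, cfg)
        v140, _ = simulate_efield(coil, 45.0, 140, mask, cfg)
        assert v140.grid.max() > v110.grid.max()

    def test_kernel_matches_scalar_closed_form(self, setup):
        """Probe voxels against an independently coded kernel evaluation."""
        cfg, mask = setup
        coil = self._center_coil(cfg, mask)
        vol, _ = simulate_efield(coil, 45.0, 120, mask, cfg)
        mask_vox = np.argwhere(mask.grid > 0)
        probes = mask_vox[:: max(1, len(mask_vox) // 5)][:5]
        peak = mask_vox[np.argmin(np.linalg.norm(
            mask_vox * cfg.voxel_size - coil, axis=1))]
        # independent scalar evaluation of amplitude * kernel
        s = (120 - 100) / 40.0
        peak_val = vol.grid[tuple(peak)]
        d_peak = np.linalg.norm(peak * cfg.voxel_size - coil)
        base = peak_val / np.exp(-d_peak ** 2 / (2 * cfg.field_sigma_mm ** 2))
        for v in probes:
            d = 0.0
            for ax in range(3):
                d += (v[ax] * cfg.voxel_size - coil[ax]) ** 2
            expected = base * np.exp(-d / (2 * cfg.field_sigma_mm ** 2))
            assert vol.grid[tuple(v)] == pytest.approx(expected, rel=1e-5)
        assert base <= cfg.field_amp_vm * s * (1 + cfg.orientation_gain) + 1e-9

    def test_far_coil_gives_zero_field_and_flag(self, setup):
        cfg, mask = setup
        coil = np.array([-500.0, -500.0, 100.0])
        vol, fringe = simulate_efield(coil, 45.0, 140, mask, cfg)
        assert fringe and vol.grid.sum() == 0

    def test_field_masked_nonnegative_unimodal(self, setup):
        cfg, mask = setup
        coil = self._center_coil(cfg, mask)
        vol, _ = simulate_efield(coil, 45.0, 130, mask, cfg)
        assert np.all(vol.grid >= 0)
        assert np.all(vol.grid[mask.grid == 0] == 0)
        # single connected superlevel set at half peak (26-connectivity:
        # the ribbon's diagonal voxel adjacencies count as connected)
        sup = vol.grid >= 0.5 * vol.grid.max()
        _, n = ndimage.label(sup, structure=np.ones((3, 3, 3)))
        assert n == 1


class TestWeightMaps:
    def test_normalised_supported_distinct(self):
        mask = make_phantom_mask((16, 16, 16), 0.05, seed=1)
        maps = make_muscle_weight_maps(15, mask, seed=0, voxel_size=4.0)
        assert len(maps) == 15
        centers = []
        for wm in maps:
            assert wm.grid.sum() == pytest.approx(1.0, abs=1e-6)
            assert np.all(wm.grid[mask.grid == 0] == 0)
            centers.append(tuple(wm.center_vox))
        assert len(set(centers)) == 15
        cmat = np.array([c for c in centers], dtype=float)
        d = np.linalg.norm(cmat[:, None] - cmat[None], axis=-1)
        assert d[~np.eye(15, dtype=bool)].min() > 0


class TestRecruitment:
    @pytest.fixture(scope="class")
    def setup(self):
        cfg = PhantomConfig.test_scale(seed=4, noise_sd=0.0)
        mask = make_phantom_mask(cfg.shape, cfg.mask_fraction, seed=4)
        maps = make_muscle_weight_maps(cfg.m, mask, seed=5,
                                       sigma_mm=cfg.muscle_sigma_mm,
                                       voxel_size=cfg.voxel_size)
        return cfg, mask, maps

    def test_zero_field_zero_mep(self, setup):
        cfg, mask, maps = setup
        from tmsinv.data import EFieldVolume
        zero = EFieldVolume(np.zeros(cfg.shape, dtype=np.float32),
                            voxel_size=cfg.voxel_size)
        mep = simulate_mep(zero, maps, cfg, np.random.default_rng(0))
        assert np.all(mep.values == 0)

    def test_strong_central_field_broader_activation(self, setup):
        cfg, mask, maps = setup
        vs = cfg.voxel_size
        centroid = np.argwhere(mask.grid > 0).mean(axis=0) * vs
        coil = np.array([centroid[0], centroid[1],
                         centroid[2] + cfg.coil_standoff_mm])
        strong, _ = simulate_efield(coil, 45.0, 140, mask, cfg)
        fringe_coil = coil + np.array([25.0, 25.0, 0.0])
        weak, _ = simulate_efield(fringe_coil, 45.0, 110, mask, cfg)
        rng = np.random.default_rng(0)
        n_strong = simulate_mep(strong, maps, cfg, rng).n_active
        n_weak = simulate_mep(weak, maps, cfg, rng).n_active
        assert n_strong > n_weak

    def test_matches_scalar_sigmoid_formula(self, setup):
        cfg, mask, maps = setup
        vs = cfg.voxel_size
        centroid = np.argwhere(mask.grid > 0).mean(axis=0) * vs
        coil = np.array([centroid[0], centroid[1],
                         centroid[2] + cfg.coil_standoff_mm])
        field, _ = simulate_efield(coil, 45.0, 130, mask, cfg)
        th = np.linspace(*cfg.recruit_threshold_range, cfg.m)
        mep = simulate_mep(field, maps, cfg, np.random.default_rng(0),
                           thresholds=th)
        for k in range(cfg.m):
            drive = float(np.sum(maps[k].grid * field.grid)) / cfg.drive_ref_vm
            act = 1 / (1 + np.exp(-cfg.recruit_slope * (drive - th[k])))
            floor = (1 / (1 + np.exp(cfg.recruit_slope * th[k]))
                     + cfg.rectify_floor)
            expected = cfg.mep_gain_uv * max(0.0, act - floor)
            assert mep.values[k] == pytest.approx(expected, abs=1e-9)


class TestDataset:
    def test_grid_design_yields_196_records(self, phantom_dataset):
        assert len(phantom_dataset) == 196
        per_int = {}
        for r in phantom_dataset:
            per_int[r.intensity_pct_rmt] = per_int.get(r.intensity_pct_rmt, 0) + 1
        assert per_int == {110: 49, 120: 49, 130: 49, 140: 49}

    def test_deterministic_given_seed(self):
        cfg = PhantomConfig.test_scale(seed=9)
        a = generate_dataset(cfg)
        b = generate_dataset(PhantomConfig.test_scale(seed=9))
        for ra, rb in zip(a.records, b.records):
            np.testing.assert_array_equal(ra.efield.grid, rb.efield.grid)
            np.testing.assert_array_equal(ra.mep.values, rb.mep.values)

    def test_mep_mean_and_variance_increase_with_intensity(self, phantom_dataset):
        stats = {}
        for I in (110, 120, 130, 140):
            mat = np.stack([r.mep.values for r in phantom_dataset
                            if r.intensity_pct_rmt == I])
            stats[I] = (mat.mean(), mat.var())
        means = [stats[I][0] for I in (110, 120, 130, 140)]
        variances = [stats[I][1] for I in (110, 120, 130, 140)]
        assert means == sorted(means)
        assert variances == sorted(variances)

    def test_zero_mep_fraction_higher_at_low_intensity(self):
        lo = generate_dataset(PhantomConfig.test_scale(
            seed=6, intensities=(110,)))
        hi = generate_dataset(PhantomConfig.test_scale(
            seed=6, intensities=(140,)))
        frac = lambda ds: np.mean([np.all(r.mep.values == 0) for r in ds])
        assert frac(lo) > frac(hi)

    def test_field_peaks_straddle_outlier_threshold(self, phantom_dataset):
        peaks = np.array([(r.efield.grid * phantom_dataset.mask.grid).max()
                          for r in phantom_dataset])
        assert (peaks[peaks > 0] < 0.010).any()
        assert (peaks > 0.010).sum() > 100

    def test_preprocessing_exercised_end_to_end(self, phantom_dataset,
                                                preprocessed_dataset):
        assert len(preprocessed_dataset) < len(phantom_dataset)
        n_active = [r.mep.n_active for r in preprocessed_dataset]
        assert min(n_active) >= 1
        assert max(n_active) >= 8  # broad central activation survives
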