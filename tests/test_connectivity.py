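"""Unit tests for seed masks, static/dynamic FC maps and smoothing."""
import numpy as np
import pytest

from seedfc import (
    Bold4D,
    DEFAULT_SEEDS,
    SeedSpec,
    WindowScheme,
    dynamic_cv_map,
    make_sphere_seed,
    sliding_window_indices,
    smooth_volume,
    static_fc_map,
    windowed_seed_correlations,
)
from seedfc.connectivity import FWHM_TO_SIGMA, Z_CLIP_EPS


def _affine(vox=3.0, origin=(0.0, 0.0, 0.0)):
    aff = np.eye(4)
    aff[:3, :3] *= vox
    aff[:3, 3] = origin
    return aff


class TestSphereSeed:
    def test_default_seed_table(self):
        byname = {s.name: s for s in DEFAULT_SEEDS}
        assert byname["PCC"].center_mni == (0.0, -53.0, 26.0)
        assert byname["PCC"].network == "DMN"
        assert byname["dACC"].center_mni == (10.0, 34.0, 24.0)
        assert byname["dlPFC"].center_mni == (30.0, 12.0, 60.0)
        assert all(s.diameter_mm == 6.0 for s in DEFAULT_SEEDS)

    def test_6mm_diameter_on_voxel_center_is_7_voxels(self):
        # 3 mm radius closed ball on a 3 mm grid: center + 6 face neighbors
        spec = SeedSpec("x", "DMN", (15.0, 15.0, 15.0), 6.0)
        mask = make_sphere_seed(spec, _affine(), (11, 11, 11))
        assert mask.sum() == 7
        assert mask[5, 5, 5]
        assert mask[4, 5, 5] and mask[6, 5, 5] and mask[5, 5, 6]
        assert not mask[4, 4, 5]  # diagonal at 4.24 mm excluded

    def test_sub_voxel_diameter_is_single_voxel(self):
        spec = SeedSpec("x", "DMN", (15.0, 15.0, 15.0), 2.9)
        assert make_sphere_seed(spec, _affine(), (11, 11, 11)).sum() == 1

    def test_half_voxel_shift_asymmetric_and_small(self):
        spec = SeedSpec("x", "DMN", (16.5, 15.0, 15.0), 6.0)
        mask = make_sphere_seed(spec, _affine(), (11, 11, 11))
        assert 0 < mask.sum() <= 7
        # asymmetric along x: reflected copies differ
        assert not np.array_equal(mask, mask[::-1, :, :])

    def test_center_outside_grid_rejected(self):
        spec = SeedSpec("x", "DMN", (200.0, 0.0, 0.0), 6.0)
        with pytest.raises(ValueError, match="outside"):
            make_sphere_seed(spec, _affine(), (11, 11, 11))


class TestStaticFcMap:
    def _bold(self, rng, n=100):
        return Bold4D(rng.standard_normal((5, 5, 5, n)), _affine(), 2.0)

    def test_self_correlation_hits_clip_bound(self, rng):
        img = self._bold(rng)
        seed = np.zeros((5, 5, 5), bool)
        seed[2, 2, 2] = True
        out = static_fc_map(img, seed)
        assert out.values[2, 2, 2] == pytest.approx(np.arctanh(1 - Z_CLIP_EPS))

    def test_orthogonal_series_gives_zero(self, rng):
        img = self._bold(rng, 64)
        seed = np.zeros((5, 5, 5), bool)
        seed[2, 2, 2] = True
        t = np.arange(64)
        data = img.data.copy()
        data[2, 2, 2] = np.sin(2 * np.pi * 4 * t / 64)
        data[0, 0, 0] = np.cos(2 * np.pi * 4 * t / 64)  # orthogonal over full cycles
        out = static_fc_map(img.with_data(data), seed)
        assert abs(out.values[0, 0, 0]) < 1e-10

    def test_matches_bruteforce_oracle_and_atanh(self, rng):
        img = self._bold(rng)
        seed = np.zeros((5, 5, 5), bool)
        seed[1, 1, 1] = seed[1, 1, 2] = True
        out = static_fc_map(img, seed)
        s = img.data[seed].mean(axis=0)
        for idx in [(0, 0, 0), (3, 4, 2), (2, 2, 2)]:
            r = np.corrcoef(img.data[idx], s)[0, 1]
            assert out.values[idx] == pytest.approx(np.arctanh(r), abs=1e-10)
        assert np.arctanh(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_constant_seed_rejected(self, rng):
        img = self._bold(rng)
        data = img.data.copy()
        data[2, 2, 2] = 5.0
        seed = np.zeros((5, 5, 5), bool)
        seed[2, 2, 2] = True
        with pytest.raises(ValueError, match="constant"):
            static_fc_map(img.with_data(data), seed)

    def test_zero_variance_voxel_flagged(self, rng):
        img = self._bold(rng)
        data = img.data.copy()
        data[0, 0, 0] = 1.5
        seed = np.zeros((5, 5, 5), bool)
        seed[2, 2, 2] = True
        out = static_fc_map(img.with_data(data), seed)
        assert out.values[0, 0, 0] == 0.0
        assert out.zero_variance[0, 0, 0]


class TestSlidingWindows:
    @pytest.mark.parametrize(
        "n,length,step,expected",
        [(200, 50, 2, 76), (200, 60, 2, 71), (50, 50, 2, 1), (10, 3, 3, 3)],
    )
    def test_window_count_formula(self, n, length, step, expected):
        wins = sliding_window_indices(n, WindowScheme(length, step))
        assert len(wins) == expected
        # enumeration oracle: every full window at multiples of step
        assert wins == [
            (a, a + length)
            for a in range(0, n - length + 1, step)
        ]

    def test_first_and_last_window(self):
        wins = sliding_window_indices(200, WindowScheme(50, 2))
        assert wins[0] == (0, 50)
        assert wins[-1] == (150, 200)

    def test_too_long_window_rejected(self):
        with pytest.raises(ValueError):
            sliding_window_indices(40, WindowScheme(50, 2))


class TestDynamicCv:
    def test_windowed_z_matches_bruteforce_loop(self, rng):
        img = Bold4D(rng.standard_normal((4, 4, 4, 90)), _affine(), 2.0)
        seed = np.zeros((4, 4, 4), bool)
        seed[1, 1, 1] = seed[2, 1, 1] = True
        scheme = WindowScheme(30, 4)
        z, mask = windowed_seed_correlations(img, seed, None, scheme)
        s = img.data[seed].mean(axis=0)
        flat = img.data.reshape(-1, 90)
        for w, (a, b) in enumerate(sliding_window_indices(90, scheme)):
            for v in [0, 17, 42, 63]:
                r = np.corrcoef(flat[v, a:b], s[a:b])[0, 1]
                assert z[w, v] == pytest.approx(np.arctanh(r), abs=1e-10)

    def test_hand_arithmetic_cv(self):
        # windowed z (0.4, 0.5, 0.6) -> sample SD 0.1, mean 0.5, CV 0.2
        zs = np.array([0.4, 0.5, 0.6])
        assert zs.std(ddof=1) / zs.mean() == pytest.approx(0.2)

    def test_constant_coupling_noiseless_gives_zero_cv(self):
        t = np.arange(120)
        s = np.sin(2 * np.pi * t / 40) + 0.5 * np.cos(2 * np.pi * t / 15)
        data = np.empty((3, 3, 3, 120))
        data[:] = s  # every voxel identical to the seed
        data[0, 0, 0] = 2.0 + 3.0 * s  # affine copy: r = 1 in every window
        img = Bold4D(data, _affine(), 2.0)
        seed = np.zeros((3, 3, 3), bool)
        seed[1, 1, 1] = True
        out = dynamic_cv_map(img, seed, scheme=WindowScheme(40, 10))
        assert abs(out.values[0, 0, 0]) < 1e-10

    def test_sd_variant_and_fallback_flag(self, rng):
        img = Bold4D(rng.standard_normal((4, 4, 4, 100)), _affine(), 2.0)
        seed = np.zeros((4, 4, 4), bool)
        seed[1, 1, 1] = True
        scheme = WindowScheme(40, 5)
        cv = dynamic_cv_map(img, seed, scheme=scheme, variability_kind="cv")
        sd = dynamic_cv_map(img, seed, scheme=scheme, variability_kind="sd")
        z, _ = windowed_seed_correlations(img, seed, None, scheme)
        np.testing.assert_allclose(sd.values.reshape(-1), z.std(axis=0, ddof=1))
        # where |mean z| < 0.05 the CV map must fall back to the SD value
        small = np.abs(z.mean(axis=0)).reshape(4, 4, 4) < 0.05
        assert small.any()
        np.testing.assert_allclose(cv.values[small], sd.values[small])
        assert cv.sd_fallback[small].all()

    def test_single_window_rejected(self, rng):
        img = Bold4D(rng.standard_normal((3, 3, 3, 50)), _affine(), 2.0)
        seed = np.zeros((3, 3, 3), bool)
        seed[1, 1, 1] = True
        with pytest.raises(ValueError, match="2 sliding windows"):
            dynamic_cv_map(img, seed, scheme=WindowScheme(50, 2))


class TestSmoothing:
    def test_zero_fwhm_is_identity(self, rng):
        x = rng.standard_normal((8, 8, 8))
        np.testing.assert_array_equal(smooth_volume(x, np.full(3, 3.0), 0.0), x)

    def test_impulse_response_is_gaussian(self):
        x = np.zeros((21, 21, 21))
        x[10, 10, 10] = 1.0
        out = smooth_volume(x, np.full(3, 3.0), 6.0)
        sigma_mm = 6.0 * FWHM_TO_SIGMA
        assert sigma_mm == pytest.approx(2.548, abs=2e-3)
        sigma_vox = sigma_mm / 3.0
        # ratios of neighbors to center follow exp(-d^2 / 2 sigma^2)
        expect = np.exp(-1.0 / (2 * sigma_vox ** 2))
        assert out[11, 10, 10] / out[10, 10, 10] == pytest.approx(expect, rel=2e-2)
        expect2 = np.exp(-2.0 / (2 * sigma_vox ** 2))
        assert out[11, 11, 10] / out[10, 10, 10] == pytest.approx(expect2, rel=2e-2)

    def test_constant_map_unchanged_and_mean_preserved(self, rng):
        mask = np.zeros((10, 10, 10), bool)
        mask[2:8, 2:8, 3:9] = True
        const = np.where(mask, 4.2, 0.0)
        out = smooth_volume(const, np.full(3, 3.0), 6.0, mask)
        np.testing.assert_allclose(out[mask], 4.2, atol=1e-12)
        x = rng.standard_normal((10, 10, 10))
        out = smooth_volume(x, np.full(3, 3.0), 6.0, mask)
        assert out[mask].mean() == pytest.approx(x[mask].mean(), abs=1e-9)
        assert np.all(out[~mask] == 0)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            smooth_volume(np.zeros((4, 4, 4)), np.full(3, 3.0), -1.0)
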