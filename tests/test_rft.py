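"""Unit tests for the group GLM, smoothness estimation and GRF clusters."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.ndimage import gaussian_filter
from scipy.special import gamma as gamma_fn

from seedfc import (
    build_design,
    estimate_smoothness,
    extract_cluster_values,
    grf_cluster_threshold,
    posthoc_pairwise,
    voxelwise_ancova,
)
from seedfc.rft import (
    SmoothnessEstimate,
    cluster_extent_p,
    expected_cluster_stats,
    gaussianize_f,
)


def _table(n_per_group=(8, 8, 8), rng=None):
    rng = rng or np.random.default_rng(0)
    rows = []
    for g, n in zip(("AD", "aMCI", "NC"), n_per_group):
        for i in range(n):
            rows.append(
                dict(
                    id=f"{g}{i}", group=g, age=rng.normal(66, 8),
                    sex=rng.choice(["M", "F"]), education=rng.normal(7, 3),
                    mmse=rng.normal(24, 4), moca=rng.normal(20, 6),
                    mean_fd=abs(rng.normal(0.1, 0.03)),
                )
            )
    return pd.DataFrame(rows)


class TestVoxelwiseAncova:
    def test_matches_textbook_oneway_anova(self, rng):
        # zero covariates: partial group F must equal the explicit
        # sums-of-squares one-way ANOVA at every voxel
        t = _table((6, 5, 7), rng)
        for c in ("age", "education", "mean_fd"):
            t[c] = 0.0
        t["sex"] = "M"
        design = build_design(t, covariates=())
        maps = rng.standard_normal((18, 4, 4, 4))
        mask = np.ones((4, 4, 4), bool)
        res = voxelwise_ancova(maps, design, mask)
        groups = t["group"].to_numpy()
        Y = maps.reshape(18, -1)
        for v in range(Y.shape[1]):
            samples = [Y[groups == g, v] for g in ("AD", "aMCI", "NC")]
            F, _ = stats.f_oneway(*samples)
            assert res.f_map.reshape(-1)[v] == pytest.approx(F, abs=1e-8)
        assert res.df1 == 2 and res.df2 == 18 - 3

    def test_covariate_absorbs_identical_response(self, rng):
        t = _table((6, 6, 6), rng)
        design = build_design(t)
        maps = np.zeros((18, 3, 3, 3))
        maps[:] = t["age"].to_numpy()[:, None, None, None]  # response == covariate
        res = voxelwise_ancova(maps, design, np.ones((3, 3, 3), bool))
        assert np.abs(res.f_map).max() <= 1e-6

    def test_null_f_follows_reference_distribution(self, rng):
        # distributional oracle: under the null the voxelwise F values
        # follow F(2, df2) (independent voxels, KS distance < 0.05)
        t = _table((10, 10, 10), rng)
        design = build_design(t)
        maps = rng.standard_normal((30, 20, 25, 10))  # 5000 voxels
        res = voxelwise_ancova(maps, design, np.ones((20, 25, 10), bool))
        d, _ = stats.kstest(res.f_map.reshape(-1), "f", args=(res.df1, res.df2))
        assert d < 0.05

    def test_f_invariant_to_covariate_rescaling(self, rng):
        t = _table((5, 5, 5), rng)
        maps = rng.standard_normal((15, 3, 3, 3))
        mask = np.ones((3, 3, 3), bool)
        f1 = voxelwise_ancova(maps, build_design(t), mask).f_map
        t2 = t.copy()
        t2["age"] = 3.7 * t2["age"] - 120.0
        f2 = voxelwise_ancova(maps, build_design(t2), mask).f_map
        np.testing.assert_allclose(f1, f2, atol=1e-8)

    def test_small_group_rejected(self, rng):
        t = _table((2, 2, 2), rng)
        t = t.drop(t[t.group == "AD"].index[0])
        with pytest.raises(ValueError, match="fewer than 2"):
            build_design(t)


class TestSmoothness:
    def test_recovers_known_kernel(self, rng):
        # white noise smoothed with an 8 mm kernel on a 3 mm grid must come
        # back within 15% (interior mask, 30 maps)
        fwhm_vox = 8.0 / 3.0
        sigma = fwhm_vox / (2 * np.sqrt(2 * np.log(2)))
        maps = np.stack(
            [gaussian_filter(rng.standard_normal((24, 24, 24)), sigma) for _ in range(30)]
        )
        mask = np.zeros((24, 24, 24), bool)
        mask[4:20, 4:20, 4:20] = True
        est = estimate_smoothness(maps, mask)
        np.testing.assert_allclose(est.fwhm_voxels, fwhm_vox, rtol=0.15)

    def test_white_noise_is_voxel_scale(self, rng):
        maps = rng.standard_normal((30, 16, 16, 16))
        est = estimate_smoothness(maps, np.ones((16, 16, 16), bool))
        assert np.all(est.fwhm_voxels < 1.5)

    def test_resels_proportional_to_mask_volume(self, rng):
        maps = np.stack(
            [gaussian_filter(rng.standard_normal((16, 16, 32)), 1.2) for _ in range(20)]
        )
        m1 = np.zeros((16, 16, 32), bool)
        m1[2:14, 2:14, 2:16] = True
        m2 = np.zeros((16, 16, 32), bool)
        m2[2:14, 2:14, 2:30] = True
        e1 = estimate_smoothness(maps, m1)
        e2 = estimate_smoothness(maps, m2)
        assert e2.resels / e1.resels == pytest.approx(2.0, rel=0.05)

    def test_degenerate_residuals_rejected(self):
        with pytest.raises(ValueError):
            estimate_smoothness(np.zeros((5, 6, 6, 6)), np.ones((6, 6, 6), bool))


class TestGrfClusters:
    def _smoothness(self):
        return SmoothnessEstimate(np.array([2.5, 2.5, 2.5]), 300.0)

    def test_empty_supra_threshold_set(self):
        f = np.zeros((8, 8, 8))
        out = grf_cluster_threshold(
            f, 2, 40, self._smoothness(), np.ones((8, 8, 8), bool), np.eye(4)
        )
        assert out == []

    def test_closed_form_reevaluation(self):
        # independent symbolic re-evaluation of the extent formulas at fixed
        # (resels, df, threshold, k)
        sm = self._smoothness()
        u = stats.norm.isf(0.001)
        assert u == pytest.approx(3.0902, abs=1e-4)
        df1, df2 = 2, 38
        Em, EN, beta = expected_cluster_stats(sm, 4000, 0.001, df1, df2)
        # F-field 3D EC density, written out from scratch
        f = stats.f.isf(0.001, df1, df2)
        k_, v = float(df1), float(df2)
        x = k_ * f / v
        rho = (
            (4 * np.log(2)) ** 1.5 / (2 * np.pi) ** 1.5 / np.sqrt(2)
            * gamma_fn((v + k_ - 3) / 2) / (gamma_fn(v / 2) * gamma_fn(k_ / 2))
            * x ** ((k_ - 3) / 2) * (1 + x) ** (-(v + k_ - 2) / 2)
            * ((v - 1) * (v - 2) * x ** 2
               - (2 * v * k_ - v - k_ - 1) * x
               + (k_ - 1) * (k_ - 2))
        )
        Em_ref = 300.0 * rho
        EN_ref = 4000 * 0.001
        beta_ref = (gamma_fn(2.5) * Em_ref / EN_ref) ** (2 / 3)
        assert Em == pytest.approx(Em_ref, rel=1e-12)
        assert EN == pytest.approx(EN_ref, rel=1e-12)
        assert beta == pytest.approx(beta_ref, rel=1e-12)
        for k in (5, 20, 80):
            p_ref = 1 - np.exp(-Em_ref * np.exp(-beta_ref * k ** (2 / 3)))
            assert cluster_extent_p(k, Em, beta) == pytest.approx(p_ref, rel=1e-12)

    def test_f_ec_density_exceeds_gaussian_at_matched_tail(self):
        # an F-derived field has more excursion components than a Gaussian
        # field of the same smoothness at the same tail probability
        from seedfc.rft import ec_density_3d_f, ec_density_3d_gauss

        f = stats.f.isf(0.001, 2, 38)
        u = stats.norm.isf(0.001)
        assert ec_density_3d_f(f, 2, 38) > ec_density_3d_gauss(u)

    def test_cluster_p_monotone_in_size(self):
        sm = self._smoothness()
        Em, _, beta = expected_cluster_stats(sm, 4000, 0.001, 2, 38)
        ps = [cluster_extent_p(k, Em, beta) for k in range(1, 200, 5)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_peak_and_members_reported(self):
        f = np.zeros((10, 10, 10))
        f[4:7, 4:6, 5] = 40.0
        f[5, 5, 5] = 55.0
        aff = np.eye(4)
        aff[:3, :3] *= 3.0
        out = grf_cluster_threshold(
            f, 2, 40, self._smoothness(), np.ones((10, 10, 10), bool), aff,
            cluster_p=1.0 - 1e-12, return_all=True,
        )
        assert len(out) == 1
        c = out[0]
        assert c.n_voxels == 6
        assert c.peak_stat == 55.0
        assert c.peak_mni == (15.0, 15.0, 15.0)

    def test_gaussianize_matches_tail_probability(self):
        f = np.full((3, 3, 3), 8.0)
        mask = np.ones((3, 3, 3), bool)
        z = gaussianize_f(f, 2, 38, mask)
        p = stats.f.sf(8.0, 2, 38)
        assert z[0, 0, 0] == pytest.approx(stats.norm.isf(p), rel=1e-10)


class TestClusterValuesAndPosthoc:
    def test_extract_matches_loop_oracle(self, rng):
        from seedfc.rft import ClusterResult

        maps = rng.standard_normal((7, 6, 6, 6))
        members = np.array([[1, 2, 3], [4, 5, 0], [2, 2, 2]])
        c = ClusterResult(1, 3, (0, 0, 0), 1.0, 0.01, members)
        vals = extract_cluster_values(maps, c)
        for i in range(7):
            expected = np.mean([maps[i][tuple(m)] for m in members])
            assert vals[i] == pytest.approx(expected, abs=1e-12)
        single = ClusterResult(1, 1, (0, 0, 0), 1.0, 0.01, members[:1])
        np.testing.assert_allclose(
            extract_cluster_values(maps, single), maps[:, 1, 2, 3]
        )

    def test_identical_groups_p_one(self):
        vals = np.tile(np.arange(10.0), 3)
        groups = np.repeat(["AD", "aMCI", "NC"], 10)
        for c in posthoc_pairwise(vals, groups):
            assert c.p_adjusted == 1.0

    def test_bonferroni_times_three(self, rng):
        vals = rng.standard_normal(30)
        groups = np.repeat(["AD", "aMCI", "NC"], 10)
        out = posthoc_pairwise(vals, groups)
        for c in out:
            assert c.p_adjusted == pytest.approx(min(1.0, c.p_raw * 3))

    def test_separated_groups_detected(self):
        # power oracle: 3 SD separation at n=20/group is detected at the
        # Bonferroni 0.01 tier in nearly all replicates
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(100):
            vals = np.concatenate(
                [rng.normal(0, 1, 20), rng.normal(3, 1, 20), rng.normal(6, 1, 20)]
            )
            groups = np.repeat(["AD", "aMCI", "NC"], 20)
            out = posthoc_pairwise(vals, groups)
            hits += all(c.p_adjusted < 0.01 for c in out)
        assert hits >= 95

    def test_missing_group_rejected(self):
        with pytest.raises(ValueError):
            posthoc_pairwise(np.arange(10.0), np.repeat(["AD", "aMCI"], 5))
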