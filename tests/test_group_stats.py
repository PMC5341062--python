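import numpy as np
import pytest
from scipy import stats

import freqphase as fp


class TestOneSampleT:
    def test_symmetric_stack_gives_zero_t(self):
        t, p = fp.one_sample_t([-1.0, 0.0, 1.0])
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_example(self):
        t, p = fp.one_sample_t([1.0, 2.0, 3.0])
        assert t == pytest.approx(2 / (1 / np.sqrt(3)), abs=1e-10)  # 3.4641
        assert p == pytest.approx(2 * stats.t.sf(t, df=2), abs=1e-12)

    def test_agrees_with_scipy_on_random_stacks(self, rng):
        for _ in range(10):
            x = rng.standard_normal(rng.integers(5, 40))
            t, p = fp.one_sample_t(x)
            ref = stats.ttest_1samp(x, 0.0)
            assert abs(t - ref.statistic) < 1e-10
            assert abs(p - ref.pvalue) < 1e-8

    def test_zero_sd_flagged_not_infinite(self):
        t, p = fp.one_sample_t([2.0, 2.0, 2.0])
        assert np.isnan(t) and np.isnan(p)

    def test_too_small_stack_rejected(self):
        with pytest.raises(ValueError):
            fp.one_sample_t([1.0])

    def test_null_rejection_rate_calibrated(self):
        # 10,000 null replicates at n=34: rejection at 0.05 within 3 binomial SE
        rng = np.random.default_rng(99)
        _, p = fp.one_sample_t_map(rng.standard_normal((34, 10_000)))
        rate = np.mean(p < 0.05)
        se = np.sqrt(0.05 * 0.95 / 10_000)
        assert abs(rate - 0.05) < 3 * se

    def test_map_matches_scalar(self, rng):
        stack = rng.standard_normal((8, 5))
        t_map, p_map = fp.one_sample_t_map(stack)
        for j in range(5):
            t, p = fp.one_sample_t(stack[:, j])
            assert t_map[j] == pytest.approx(t, abs=1e-12)
            assert p_map[j] == pytest.approx(p, abs=1e-12)


def t_volume(shape, blobs, t_high=10.0):
    """Zero t map with rectangular suprathreshold blobs planted."""
    vol = np.zeros(shape)
    for corner, size, sign in blobs:
        sl = tuple(slice(c, c + s) for c, s in zip(corner, size))
        vol[sl] = sign * t_high
    return vol


class TestThresholdSPM:
    def test_extent_threshold_keeps_only_large_blob(self):
        # 120-voxel blob survives k=100; 50-voxel blob does not
        vol = t_volume((30, 30, 10), [((2, 2, 2), (6, 5, 4), +1),     # 120
                                      ((20, 20, 2), (5, 5, 2), +1)])  # 50
        spm, table = fp.threshold_spm(vol, df=19, voxel_p=1e-4, cluster_k=100)
        assert spm.n_clusters == 1
        assert table.loc[0, "size_voxels"] == 120

    def test_all_zero_map_has_no_clusters(self):
        spm, table = fp.threshold_spm(np.zeros((10, 10, 5)), df=19,
                                      voxel_p=1e-4, cluster_k=10)
        assert spm.n_clusters == 0
        assert table.empty

    def test_face_touching_blobs_merge_at_connectivity_6(self):
        shape = (30, 30, 10)
        touching = t_volume(shape, [((2, 2, 2), (5, 4, 3), +1),    # 60
                                    ((7, 2, 2), (5, 4, 3), +1)])   # 60, shares face
        spm, table = fp.threshold_spm(touching, df=19, voxel_p=1e-4,
                                      cluster_k=100, connectivity=6)
        assert spm.n_clusters == 1
        assert table.loc[0, "size_voxels"] == 120
        separated = t_volume(shape, [((2, 2, 2), (5, 4, 3), +1),
                                     ((8, 2, 2), (5, 4, 3), +1)])  # 1-voxel gap
        spm, _ = fp.threshold_spm(separated, df=19, voxel_p=1e-4,
                                  cluster_k=100, connectivity=6)
        assert spm.n_clusters == 0

    def test_opposite_signs_never_merge(self):
        vol = t_volume((20, 20, 8), [((2, 2, 2), (4, 4, 4), +1),
                                     ((6, 2, 2), (4, 4, 4), -1)])  # adjacent
        spm, table = fp.threshold_spm(vol, df=19, voxel_p=1e-4, cluster_k=10)
        assert spm.n_clusters == 2
        signs = sorted(np.sign(table["peak_t"]))
        assert signs == [-1.0, 1.0]

    def test_raising_extent_threshold_is_monotone(self, rng):
        vol = rng.standard_normal((16, 16, 8)) * 8
        counts = []
        for k in (1, 5, 20, 100):
            spm, _ = fp.threshold_spm(vol, df=19, voxel_p=1e-3, cluster_k=k)
            counts.append(int((spm.cluster_labels > 0).sum()))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_mask_respected_and_empty_mask_rejected(self):
        vol = t_volume((10, 10, 5), [((0, 0, 0), (3, 3, 3), +1)])
        mask = np.zeros(vol.shape, dtype=bool)
        with pytest.raises(ValueError, match="empty"):
            fp.threshold_spm(vol, df=19, voxel_p=1e-4, cluster_k=1, mask=mask)
        mask[5:, :, :] = True  # excludes the blob
        spm, _ = fp.threshold_spm(vol, df=19, voxel_p=1e-4, cluster_k=1, mask=mask)
        assert spm.n_clusters == 0

    def test_peak_coordinates_in_mm_with_affine(self):
        vol = t_volume((10, 10, 5), [((4, 5, 2), (1, 1, 1), +1)])
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        _, table = fp.threshold_spm(vol, df=19, voxel_p=1e-4, cluster_k=1,
                                    affine=affine)
        assert tuple(table.loc[0, ["peak_x_mm", "peak_y_mm", "peak_z_mm"]]) == (
            12.0, 15.0, 6.0)


class TestMonteCarloThreshold:
    def test_deterministic_under_fixed_seed(self):
        mask = np.ones((16, 16, 8), dtype=bool)
        kwargs = dict(smoothness_fwhm_mm=6.0, voxel_size_mm=3.0,
                      voxel_p=0.01, corrected_p=0.05, n_iter=100, rng_seed=5)
        assert fp.mc_cluster_threshold(mask, **kwargs) == (
            fp.mc_cluster_threshold(mask, **kwargs))

    def test_unsmoothed_null_gives_tiny_clusters(self):
        # expected suprathreshold count ~ 1e-4 * 32768: isolated voxels dominate
        mask = np.ones((32, 32, 32), dtype=bool)
        k = fp.mc_cluster_threshold(mask, smoothness_fwhm_mm=0.0,
                                    voxel_size_mm=3.0, voxel_p=1e-4,
                                    corrected_p=0.01, n_iter=200, rng_seed=0)
        assert 1 <= k <= 5

    def test_threshold_nondecreasing_in_smoothness(self):
        mask = np.ones((20, 20, 12), dtype=bool)
        common = dict(voxel_size_mm=3.0, voxel_p=0.005, corrected_p=0.05,
                      n_iter=150, rng_seed=11)
        k0 = fp.mc_cluster_threshold(mask, smoothness_fwhm_mm=0.0, **common)
        k8 = fp.mc_cluster_threshold(mask, smoothness_fwhm_mm=8.0, **common)
        assert k8 >= k0

    def test_invalid_arguments_rejected(self):
        mask = np.ones((8, 8, 4), dtype=bool)
        with pytest.raises(ValueError):
            fp.mc_cluster_threshold(np.zeros((8, 8, 4), dtype=bool))
        with pytest.raises(ValueError):
            fp.mc_cluster_threshold(mask, n_iter=10)
        with pytest.raises(ValueError):
            fp.mc_cluster_threshold(mask, corrected_p=1.5)
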