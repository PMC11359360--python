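"""Outlier filtering, normalization, resampling and augmentation."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist, pdist

from stemseg.datasets import DatasetManifest
from stemseg.io import LabeledCloud, read_cloud, write_cloud
from stemseg.preprocess import AugmentParams, FilterParams, augment_jitter, \
    augment_noise, augment_rotation, build_augmented, normalize, \
    resample_fixed, statistical_outlier_removal


def sor_bruteforce(points, k, std_ratio):
    """All-pairs reference implementation of the statistical filter."""
    d = cdist(points, points)
    np.fill_diagonal(d, np.inf)
    mean_d = np.sort(d, axis=1)[:, :k].mean(axis=1)
    thr = mean_d.mean() + std_ratio * mean_d.std()
    return np.flatnonzero(mean_d > thr)


class TestStatisticalOutlierRemoval:
    def test_planted_far_outlier_removed_exactly(self, rng):
        pts = rng.uniform(-1, 1, (200, 3))
        pts /= np.maximum(np.linalg.norm(pts, axis=1, keepdims=True), 1.0)
        pts = np.vstack([pts, [[100.0, 0.0, 0.0]]])
        labels = np.concatenate([np.zeros(200, dtype=int), [1]])
        cloud = LabeledCloud(pts, labels)
        kept, removed = statistical_outlier_removal(
            cloud, FilterParams(k_neighbors=16, std_ratio=2.0))
        np.testing.assert_array_equal(removed, [200])
        assert len(kept) == 200
        assert (kept.labels == 0).all()  # the outlier's label went with it

    def test_uniform_grid_keeps_everything(self):
        g = np.linspace(0, 1, 6)
        pts = np.array(np.meshgrid(g, g, g)).reshape(3, -1).T
        kept, removed = statistical_outlier_removal(
            LabeledCloud(pts), FilterParams(k_neighbors=6, std_ratio=3.0))
        assert removed.size == 0 and len(kept) == len(pts)

    def test_idempotent_on_far_outlier_fixture(self):
        # grid inliers: mean-kNN spread stays below 3 sigma by construction,
        # so after the far point is gone a second pass removes nothing
        g = np.linspace(0, 1, 6)
        grid = np.array(np.meshgrid(g, g, g)).reshape(3, -1).T
        pts = np.vstack([grid, [[30.0, 30.0, 30.0]]])
        params = FilterParams(k_neighbors=6, std_ratio=3.0)
        once, removed1 = statistical_outlier_removal(LabeledCloud(pts), params)
        np.testing.assert_array_equal(removed1, [216])
        twice, removed2 = statistical_outlier_removal(once, params)
        assert removed2.size == 0
        np.testing.assert_array_equal(once.points, twice.points)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 400))
        pts = rng.standard_normal((n, 3)) * rng.uniform(0.5, 2.0)
        k = int(rng.integers(3, 20))
        ratio = float(rng.uniform(1.0, 3.0))
        _, removed = statistical_outlier_removal(
            LabeledCloud(pts), FilterParams(k, ratio))
        np.testing.assert_array_equal(removed, sor_bruteforce(pts, k, ratio))

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError, match="k_neighbors"):
            statistical_outlier_removal(
                LabeledCloud(np.zeros((5, 3)) + np.arange(5)[:, None]),
                FilterParams(k_neighbors=10))


class TestNormalize:
    def test_closed_form_two_points(self):
        cloud, _ = normalize(LabeledCloud([[0, 0, 0], [2, 0, 0]]))
        np.testing.assert_allclose(cloud.points, [[-1, 0, 0], [1, 0, 0]],
                                   atol=1e-12)

    def test_round_trip(self, rng):
        pts = rng.uniform(-30, 70, (40, 3))
        normed, rec = normalize(LabeledCloud(pts))
        np.testing.assert_allclose(rec.invert(normed.points), pts, atol=1e-9)

    def test_idempotent(self, rng):
        normed, _ = normalize(LabeledCloud(rng.uniform(-1, 1, (40, 3))))
        again, _ = normalize(normed)
        np.testing.assert_allclose(again.points, normed.points, atol=1e-9)

    def test_single_point_degenerate(self):
        cloud, rec = normalize(LabeledCloud([[5, 5, 5]]))
        np.testing.assert_allclose(cloud.points, [[0, 0, 0]])
        assert rec.scale == 1.0


class TestResampleFixed:
    def test_downsample_distinct_indices(self, rng):
        cloud = LabeledCloud(rng.uniform(-1, 1, (8192, 3)))
        out = resample_fixed(cloud, 4096, seed=0)
        assert len(out) == 4096
        assert len(np.unique(out.points, axis=0)) == 4096

    def test_upsample_draws_from_originals_only(self, rng):
        pts = rng.uniform(-1, 1, (1000, 3))
        out = resample_fixed(LabeledCloud(pts), 4096, seed=1)
        assert len(out) == 4096
        present = cdist(out.points, pts).min(axis=1)
        assert present.max() == 0.0

    def test_equal_size_preserves_point_set(self, rng):
        pts = rng.uniform(-1, 1, (256, 3))
        out = resample_fixed(LabeledCloud(pts), 256, seed=2)
        np.testing.assert_allclose(np.sort(out.points, axis=0),
                                   np.sort(pts, axis=0), atol=0)


class TestAugmentations:
    def test_rotation_identity_at_zero_angle(self, tiny_cloud, rng):
        out = augment_rotation(tiny_cloud, rng, angle=0.0)
        np.testing.assert_allclose(out.points, tiny_cloud.points, atol=1e-12)

    def test_rotation_pi_flips_x(self, rng):
        cloud = LabeledCloud([[1, 0, 0], [-1, 0, 0]])  # centroid at origin
        out = augment_rotation(cloud, rng, angle=np.pi)
        np.testing.assert_allclose(out.points, [[-1, 0, 0], [1, 0, 0]],
                                   atol=1e-12)

    def test_rotation_is_an_isometry(self, tiny_cloud, rng):
        out = augment_rotation(tiny_cloud, rng)
        np.testing.assert_allclose(pdist(out.points), pdist(tiny_cloud.points),
                                   atol=1e-9)

    def test_jitter_zero_sigma_identity(self, tiny_cloud, rng):
        params = AugmentParams(jitter_sigma=0.0, jitter_clip=0.0)
        out = augment_jitter(tiny_cloud, params, rng)
        np.testing.assert_array_equal(out.points, tiny_cloud.points)

    def test_jitter_respects_clip(self, rng):
        cloud = LabeledCloud(np.zeros((4096, 3)) + [[0, 0, 1]])
        params = AugmentParams(jitter_sigma=0.5, jitter_clip=0.5)
        out = augment_jitter(cloud, params, rng)
        assert np.abs(out.points - cloud.points).max() <= 0.5

    def test_jitter_sigma_moment(self, rng):
        cloud = LabeledCloud(np.zeros((4096, 3)))
        params = AugmentParams(jitter_sigma=0.01, jitter_clip=0.05)
        out = augment_jitter(cloud, params, rng)
        assert np.std(out.points) == pytest.approx(0.01, rel=0.1)

    def test_noise_zero_sigma_identity_and_size(self, tiny_cloud, rng):
        params = AugmentParams(noise_sigma=0.0)
        out = augment_noise(tiny_cloud, params, rng)
        assert len(out) == len(tiny_cloud)
        np.testing.assert_array_equal(out.points, tiny_cloud.points)

    def test_noise_variance_adds(self, rng):
        pts = rng.normal(0, 0.1, (10_000, 3))
        params = AugmentParams(noise_sigma=0.05)
        out = augment_noise(LabeledCloud(pts), params, rng)
        got = out.points.var(axis=0).mean()
        expected = pts.var(axis=0).mean() + 0.05**2
        assert got == pytest.approx(expected, rel=0.05)

    def test_labels_preserved_by_all_augmentations(self, tiny_cloud, rng):
        params = AugmentParams()
        for out in (augment_rotation(tiny_cloud, rng),
                    augment_jitter(tiny_cloud, params, rng),
                    augment_noise(tiny_cloud, params, rng)):
            np.testing.assert_array_equal(out.labels, tiny_cloud.labels)


class TestBuildAugmented:
    def make_files(self, tmp_path, rng, n):
        rows = []
        for i in range(n):
            cloud = LabeledCloud(rng.uniform(-1, 1, (64, 3)),
                                 rng.integers(0, 2, 64))
            path = str(tmp_path / f"org{i}.ply")
            write_cloud(cloud, path)
            rows.append({"path": path, "origin_id": f"org{i}",
                         "variant": "original", "split": "none"})
        return DatasetManifest(pd.DataFrame(rows))

    def test_four_fold_expansion(self, tmp_path, rng):
        manifest = self.make_files(tmp_path, rng, 5)
        out = build_augmented(manifest, AugmentParams(seed=0))
        assert len(out) == 20
        variants = set(out.entries["variant"])
        assert variants == {"original", "rotated", "jittered", "noised"}

    def test_origin_preserved_and_files_readable(self, tmp_path, rng):
        manifest = self.make_files(tmp_path, rng, 1)
        out = build_augmented(manifest, AugmentParams(seed=0))
        assert len(out) == 4
        assert set(out.entries["origin_id"]) == {"org0"}
        for p in out.entries["path"]:
            assert len(read_cloud(p)) == 64
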