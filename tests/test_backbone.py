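"""Sampling, grouping, interpolation and the full encoder/decoder."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from stemseg.autograd import Tensor, no_grad
from stemseg.backbone import StemSegNet, farthest_point_sample, \
    group_neighbors, interpolation_weights
from stemseg.config import ModelConfig


def fps_oracle(coords, m, start=0):
    """Brute-force greedy max-min reference."""
    chosen = [start]
    best = np.linalg.norm(coords - coords[start], axis=1)
    for _ in range(m - 1):
        nxt = int(np.argmax(best))
        chosen.append(nxt)
        best = np.minimum(best, np.linalg.norm(coords - coords[nxt], axis=1))
    return np.array(chosen)


class TestFarthestPointSampling:
    def test_single_pick_is_start_index(self, rng):
        pts = rng.uniform(0, 1, (10, 3))
        np.testing.assert_array_equal(farthest_point_sample(pts, 1, 4), [4])

    def test_unit_square_second_pick_is_opposite_corner(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
        idx = farthest_point_sample(pts, 2, start_index=0)
        assert idx[1] == 3  # (1,1) is farthest from (0,0)

    @pytest.mark.parametrize("n,m", [(50, 8), (64, 64), (30, 1), (17, 9)])
    def test_equals_bruteforce_oracle(self, rng, n, m):
        pts = rng.standard_normal((n, 3))
        np.testing.assert_array_equal(farthest_point_sample(pts, m),
                                      fps_oracle(pts, m))

    def test_indices_unique(self, rng):
        idx = farthest_point_sample(rng.standard_normal((64, 3)), 32)
        assert len(np.unique(idx)) == 32

    def test_oversampling_errors(self, rng):
        with pytest.raises(ValueError):
            farthest_point_sample(rng.standard_normal((5, 3)), 6)


class TestGrouping:
    def test_infinite_radius_full_k_covers_cloud(self, rng):
        pts = rng.uniform(0, 1, (20, 3))
        idx, rel = group_neighbors(pts, np.array([0, 5]), np.inf, 20)
        for row in idx:
            assert set(row) == set(range(20))

    def test_isolated_centroid_repeats_itself(self):
        pts = np.vstack([np.zeros((1, 3)), np.full((9, 3), 10.0)
                         + np.arange(9)[:, None]])
        idx, rel = group_neighbors(pts, np.array([0]), radius=1.0, k=4)
        np.testing.assert_array_equal(idx[0], [0, 0, 0, 0])
        np.testing.assert_array_equal(rel[0], np.zeros((4, 3)))

    def test_matches_bruteforce_range_query(self, rng):
        pts = rng.uniform(0, 1, (100, 3))
        centroids = np.array([3, 50, 99])
        radius, k = 0.3, 8
        idx, rel = group_neighbors(pts, centroids, radius, k)
        d = cdist(pts[centroids], pts)
        for row, (ci, got) in enumerate(zip(centroids, idx)):
            in_ball = np.flatnonzero(d[row] <= radius)
            expected = in_ball[np.argsort(d[row][in_ball], kind="stable")][:k]
            np.testing.assert_array_equal(got[: len(expected)], expected)
            # padding repeats the nearest in-ball point
            assert (got[len(expected):] == expected[0]).all()
        np.testing.assert_allclose(rel, pts[idx] - pts[centroids][:, None],
                                   atol=0)


class TestInterpolation:
    def test_weights_sum_to_one(self, rng):
        idx, w = interpolation_weights(rng.uniform(0, 1, (40, 3)),
                                       rng.uniform(0, 1, (10, 3)))
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-9)
        assert (w >= 0).all()

    def test_coincident_point_takes_full_weight(self, rng):
        coarse = rng.uniform(0, 1, (10, 3))
        fine = np.vstack([coarse[4], rng.uniform(0, 1, (5, 3))])
        idx, w = interpolation_weights(fine, coarse)
        assert idx[0, 0] == 4
        assert w[0, 0] > 0.999  # 1/(0+eps) dominates

    def test_fewer_than_three_coarse_points(self, rng):
        idx, w = interpolation_weights(rng.uniform(0, 1, (7, 3)),
                                       rng.uniform(0, 1, (2, 3)))
        assert idx.shape == (7, 3) and w.shape == (7, 3)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-9)


class TestArchitecture:
    def test_point_and_channel_schedule(self):
        cfg = ModelConfig()
        assert cfg.point_schedule == [4096, 1024, 256, 64, 16]
        assert cfg.channels == [64, 128, 256, 512, 1024]
        assert cfg.decoder_channels == [512, 256, 128, 64]

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(n_points=1000).validate()  # not divisible by 256
        with pytest.raises(ValueError):
            ModelConfig(channels=[64, 128]).validate()

    def test_set_abstraction_quarters_points(self, tiny_model_config):
        net = StemSegNet(tiny_model_config)
        x = np.random.default_rng(0).uniform(-1, 1, (1, 256, 3))
        feats = net.lift(Tensor(np.swapaxes(x, 1, 2).astype(np.float32)))
        out, coords = net.sa_stages[0](feats, x)
        assert out.shape == (1, 16, 64)
        assert coords.shape == (1, 64, 3)

    def test_forward_probability_rows_sum_to_one(self, tiny_model_config):
        net = StemSegNet(tiny_model_config).eval()
        x = np.random.default_rng(1).uniform(-1, 1, (2, 256, 3))
        with no_grad():
            probs = net.forward(x)
        assert probs.shape == (2, 256, 2)
        np.testing.assert_allclose(probs.data.sum(axis=2), 1.0, atol=1e-6)

    def test_identical_clouds_identical_outputs(self, tiny_model_config):
        net = StemSegNet(tiny_model_config).eval()
        one = np.random.default_rng(2).uniform(-1, 1, (1, 256, 3))
        batch = np.repeat(one, 2, axis=0)
        with no_grad():
            probs = net.forward(batch)
        np.testing.assert_allclose(probs.data[0], probs.data[1], atol=1e-6)

    def test_permutation_equivariance_with_fixed_start(self, tiny_model_config):
        """Permuting points (keeping the FPS start point) permutes outputs."""
        net = StemSegNet(tiny_model_config).eval()
        rng = np.random.default_rng(3)
        x = rng.uniform(-1, 1, (1, 256, 3))
        perm = np.concatenate([[0], 1 + rng.permutation(255)])
        with no_grad():
            a = net.forward(x).data[0]
            b = net.forward(x[:, perm]).data[0]
        np.testing.assert_allclose(b, a[perm], atol=1e-4)

    def test_wrong_point_count_mentions_resampling(self, tiny_model_config):
        net = StemSegNet(tiny_model_config)
        with pytest.raises(ValueError, match="resample"):
            net.forward(np.zeros((1, 100, 3)))

    def test_ablation_switches_change_module_presence(self, tiny_model_config):
        from dataclasses import replace
        from stemseg.attention import CRAMLP, PlainMLP

        full = StemSegNet(tiny_model_config)
        bare = StemSegNet(replace(tiny_model_config, cra_enabled=False,
                                  pesa_enabled=False))
        assert isinstance(full.sa_stages[0].mlp, CRAMLP)
        assert isinstance(bare.sa_stages[0].mlp, PlainMLP)
        # default placement: one attention block at the bottleneck
        assert full.pesa_stages[-1] is not None
        assert full.pesa_stages[0] is None
        assert all(p is None for p in bare.pesa_stages)
        everywhere = StemSegNet(replace(tiny_model_config, pesa_placement="all"))
        assert all(p is not None for p in everywhere.pesa_stages)
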