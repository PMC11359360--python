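"""Hierarchical encoder/decoder for point-cloud semantic segmentation.

The encoder applies four set-abstraction stages, each retaining 25% of the
points (farthest-point sampling), grouping each centroid's ball neighborhood,
and pooling a shared per-group perceptron (CRA-MLP when enabled) over the
group. The decoder mirrors it with four feature-propagation stages that
interpolate features back to finer resolutions by inverse-distance weighting
of the three nearest coarse points, fused with U-Net-style encoder skips.
PESA blocks sit on the output of every set-abstraction stage (configurable to
bottleneck-only), fed with that stage's centroid coordinates.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .attention import PESA, make_mlp
from .autograd import Tensor, concat, no_grad
from .config import ModelConfig
from .nn import BatchNorm, Dropout, Module, PointwiseConv

__all__ = ["farthest_point_sample", "group_neighbors", "interpolation_weights",
           "SetAbstraction", "FeaturePropagation", "StemSegNet"]


def farthest_point_sample(coords: np.ndarray, m: int, start_index: int = 0
                          ) -> np.ndarray:
    """Greedy max-min subsampling of `m` indices from (N, 3) coords.

    The first pick is `start_index`; every subsequent pick maximizes its
    distance to the already-chosen set. Returned indices are unique.
    """
    n = len(coords)
    if m > n:
        raise ValueError(f"cannot sample {m} points from {n}")
    if m < 1:
        raise ValueError("m must be >= 1")
    return _fps_batch(np.asarray(coords, dtype=float)[None], m, start_index)[0]


def _fps_batch(coords: np.ndarray, m: int, start_index: int = 0) -> np.ndarray:
    """Batched greedy max-min sampling on (B, N, 3) coords -> (B, m) indices.

    Runs on squared distances (same argmax as Euclidean)."""
    b, n, _ = coords.shape
    sq = np.einsum("bnd,bnd->bn", coords, coords)
    rows = np.arange(b)
    chosen = np.empty((b, m), dtype=np.int64)
    chosen[:, 0] = start_index
    picked = coords[:, start_index]
    best = sq + sq[:, start_index, None] - 2 * np.einsum("bnd,bd->bn", coords, picked)
    for i in range(1, m):
        nxt = np.argmax(best, axis=1)
        chosen[:, i] = nxt
        picked = coords[rows, nxt]
        d = sq + sq[rows, nxt, None] - 2 * np.einsum("bnd,bd->bn", coords, picked)
        np.minimum(best, d, out=best)
    return chosen


def group_neighbors(coords: np.ndarray, centroid_indices: np.ndarray,
                    radius: float, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Ball query: up to `k` nearest points within `radius` of each centroid.

    Neighborhoods short of `k` points are padded by repeating the nearest
    in-ball point (the centroid itself, at distance zero, is always in-ball).
    Returns (indices (M, K), relative coords (M, K, 3) = neighbor - centroid).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    centroids = coords[centroid_indices]
    d = cdist(centroids, coords, "sqeuclidean")  # (M, N)
    radius = radius * radius
    k_eff = min(k, coords.shape[0])
    if k_eff < coords.shape[0]:
        part = np.argpartition(d, k_eff - 1, axis=1)[:, :k_eff]
        rows0 = np.arange(len(centroids))[:, None]
        order = np.take_along_axis(
            part, np.argsort(d[rows0, part], axis=1, kind="stable"), axis=1)
    else:
        order = np.argsort(d, axis=1, kind="stable")[:, :k_eff]
    if k_eff < k:  # fewer points than k: start from repeats of the nearest
        order = np.concatenate(
            [order, np.repeat(order[:, :1], k - k_eff, axis=1)], axis=1)
    rows = np.arange(len(centroids))[:, None]
    within = d[rows, order] <= radius
    idx = np.where(within, order, order[:, :1])
    rel = coords[idx] - centroids[:, None, :]
    return idx, rel


def _group_batch(coords: np.ndarray, centroid_idx: np.ndarray, radius: float,
                 k: int) -> tuple[np.ndarray, np.ndarray]:
    """Batched ball query. coords (B, N, 3), centroid_idx (B, M) ->
    (indices (B, M, K), relative coords (B, M, K, 3))."""
    b, n, _ = coords.shape
    rows = np.arange(b)[:, None]
    centroids = coords[rows, centroid_idx]  # (B, M, 3)
    sq_a = np.einsum("bnd,bnd->bn", coords, coords)
    sq_c = np.einsum("bmd,bmd->bm", centroids, centroids)
    d = sq_c[:, :, None] + sq_a[:, None, :] - 2 * np.matmul(
        centroids, np.swapaxes(coords, 1, 2))  # squared distances (B, M, N)
    r2 = radius * radius
    k_eff = min(k, n)
    if k_eff < n:
        part = np.argpartition(d, k_eff - 1, axis=2)[:, :, :k_eff]
        dpart = np.take_along_axis(d, part, axis=2)
        order = np.take_along_axis(part, np.argsort(dpart, axis=2, kind="stable"),
                                   axis=2)
    else:
        order = np.argsort(d, axis=2, kind="stable")[:, :, :k_eff]
    if k_eff < k:
        order = np.concatenate(
            [order, np.repeat(order[:, :, :1], k - k_eff, axis=2)], axis=2)
    within = np.take_along_axis(d, order, axis=2) <= r2
    idx = np.where(within, order, order[:, :, :1])
    rel = coords[rows[:, :, None], idx] - centroids[:, :, None, :]
    return idx, rel


def _interp_batch(fine: np.ndarray, coarse: np.ndarray, k: int = 3,
                  eps: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Batched 3-NN inverse-distance weights: (B, Nf, 3), (B, Nc, 3) ->
    (idx (B, Nf, k), weights (B, Nf, k))."""
    b, nf, _ = fine.shape
    nc = coarse.shape[1]
    sq_f = np.einsum("bnd,bnd->bn", fine, fine)
    sq_c = np.einsum("bnd,bnd->bn", coarse, coarse)
    d = sq_f[:, :, None] + sq_c[:, None, :] - 2 * np.matmul(
        fine, np.swapaxes(coarse, 1, 2))
    np.maximum(d, 0.0, out=d)
    k_eff = min(k, nc)
    if k_eff < nc:
        part = np.argpartition(d, k_eff - 1, axis=2)[:, :, :k_eff]
        dpart = np.take_along_axis(d, part, axis=2)
        idx = np.take_along_axis(part, np.argsort(dpart, axis=2, kind="stable"),
                                 axis=2)
    else:
        idx = np.argsort(d, axis=2, kind="stable")[:, :, :k_eff]
    w = 1.0 / (np.sqrt(np.take_along_axis(d, idx, axis=2)) + eps)
    w /= w.sum(axis=2, keepdims=True)
    if k_eff < k:
        idx = np.concatenate([idx, np.repeat(idx[:, :, :1], k - k_eff, axis=2)],
                             axis=2)
        w = np.concatenate([w, np.zeros((b, nf, k - k_eff))], axis=2)
    return idx, w


def interpolation_weights(fine_coords: np.ndarray, coarse_coords: np.ndarray,
                          k: int = 3, eps: float = 1e-8
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-distance weights of the k nearest coarse points per fine point.

    w_j = 1 / (d_j + eps), normalized to sum to 1. Returns (idx (Nf, k),
    weights (Nf, k)).
    """
    k_eff = min(k, len(coarse_coords))
    d = cdist(fine_coords, coarse_coords, "sqeuclidean")
    rows = np.arange(len(fine_coords))[:, None]
    if k_eff < len(coarse_coords):
        part = np.argpartition(d, k_eff - 1, axis=1)[:, :k_eff]
        idx = np.take_along_axis(
            part, np.argsort(d[rows, part], axis=1, kind="stable"), axis=1)
    else:
        idx = np.argsort(d, axis=1, kind="stable")[:, :k_eff]
    w = 1.0 / (np.sqrt(d[rows, idx]) + eps)
    w /= w.sum(axis=1, keepdims=True)
    if k_eff < k:
        idx = np.concatenate([idx, np.repeat(idx[:, :1], k - k_eff, axis=1)], axis=1)
        w = np.concatenate([w, np.zeros((len(w), k - k_eff))], axis=1)
    return idx, w


class SetAbstraction(Module):
    """One encoder stage: FPS to 25% of the points, ball grouping, shared
    per-group perceptron, max-pool over each group."""

    def __init__(self, in_channels: int, out_channels: int, radius: float,
                 k: int, rng: np.random.Generator, cra: bool,
                 se_reduction: int = 4):
        super().__init__()
        self.radius = radius
        self.k = k
        self.out_channels = out_channels
        widths = [max(out_channels // 2, 8), out_channels]
        self.mlp = make_mlp(in_channels + 3, widths, rng, cra, se_reduction)

    def forward(self, features: Tensor, coords: np.ndarray
                ) -> tuple[Tensor, np.ndarray]:
        """features: (B, C, N), coords: (B, N, 3) -> ((B, C', N/4), (B, N/4, 3))."""
        b, _, n = features.shape
        if n % 4:
            raise ValueError(f"point count {n} not divisible by 4")
        m = n // 4
        centroid_idx = _fps_batch(coords, m)
        idx_all, rel_all = _group_batch(coords, centroid_idx, self.radius, self.k)
        new_coords = coords[np.arange(b)[:, None], centroid_idx]
        gathered = features.gather_points(idx_all)        # (B, C, M, K)
        rel_t = Tensor(np.moveaxis(rel_all, 3, 1).astype(np.float32))
        grouped = concat([gathered, rel_t], axis=1)       # (B, C+3, M, K)
        lifted = self.mlp(grouped)                        # (B, C', M, K)
        pooled = lifted.max(axis=3)                       # (B, C', M)
        return pooled, new_coords


class FeaturePropagation(Module):
    """One decoder stage: 3-NN inverse-distance interpolation of the coarse
    features onto the finer positions, concatenation with the encoder skip,
    and a pointwise perceptron to the stage width."""

    def __init__(self, coarse_channels: int, skip_channels: int,
                 out_channels: int, rng: np.random.Generator, cra: bool,
                 se_reduction: int = 4):
        super().__init__()
        self.out_channels = out_channels
        widths = [out_channels, out_channels]
        self.mlp = make_mlp(coarse_channels + skip_channels, widths, rng, cra,
                            se_reduction)

    def forward(self, coarse: Tensor, coarse_coords: np.ndarray,
                fine_coords: np.ndarray, skip: Tensor) -> Tensor:
        idx_all, w_all = _interp_batch(fine_coords, coarse_coords)
        gathered = coarse.gather_points(idx_all)            # (B, C, Nf, 3)
        weights = Tensor(w_all[:, None, :, :].astype(np.float32))
        interpolated = (gathered * weights).sum(axis=3)     # (B, C, Nf)
        fused = concat([interpolated, skip], axis=1)
        return self.mlp(fused)


class StemSegNet(Module):
    """Full segmentation network: per-point lift, four set-abstraction stages
    with optional PESA, four feature-propagation stages, per-point class head.

    ``forward`` takes a (B, N, 3) batch of normalized coordinates and returns
    per-point class probabilities (B, N, num_classes).
    """

    def __init__(self, config: ModelConfig):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch = config.channels
        self.lift = make_mlp(3, [ch[0], ch[0]], rng, config.cra_enabled,
                             config.se_reduction)
        self.sa_stages = [
            SetAbstraction(ch[s], ch[s + 1], config.radii[s], config.group_size,
                           rng, config.cra_enabled, config.se_reduction)
            for s in range(config.stages)]
        for i, st in enumerate(self.sa_stages):
            self.register_module(f"sa{i + 1}", st)
        self.pesa_stages: list = []
        if config.pesa_enabled:
            for s in range(config.stages):
                use = (config.pesa_placement == "all"
                       or s == config.stages - 1)
                block = PESA(ch[s + 1], rng, config.se_reduction,
                             config.position_gate) if use else None
                self.pesa_stages.append(block)
                if block is not None:
                    self.register_module(f"pesa{s + 1}", block)
        else:
            self.pesa_stages = [None] * config.stages
        dec = config.decoder_channels
        skips = list(reversed(ch[:-1]))   # encoder widths at matching levels
        coarse_in = ch[-1]
        self.fp_stages = []
        for s in range(config.stages):
            fp = FeaturePropagation(coarse_in, skips[s], dec[s], rng,
                                    config.cra_enabled, config.se_reduction)
            self.fp_stages.append(fp)
            self.register_module(f"fp{s + 1}", fp)
            coarse_in = dec[s]
        # per-point head: hidden conv-BN-ReLU block, dropout, classifier
        self.head_hidden = PointwiseConv(dec[-1], dec[-1], rng)
        self.head_bn = BatchNorm(dec[-1])
        self.head_dropout = Dropout(config.head_dropout,
                                    np.random.default_rng(config.seed + 1))
        self.head = PointwiseConv(dec[-1], config.num_classes, rng)

    def forward(self, points: np.ndarray, return_logits: bool = False) -> Tensor:
        points = np.asarray(points, dtype=np.float32)
        if points.ndim == 2:
            points = points[None]
        b, n, _ = points.shape
        if n != self.config.n_points:
            raise ValueError(
                f"expected {self.config.n_points} points per cloud, got {n}; "
                "resample the cloud first (preprocess.resample_fixed)")
        feats = Tensor(np.swapaxes(points, 1, 2).astype(np.float32))  # (B, 3, N)
        feats = self.lift(feats)
        coords = points
        skip_feats = [feats]
        skip_coords = [coords]
        for stage, pesa in zip(self.sa_stages, self.pesa_stages):
            feats, coords = stage(feats, coords)
            if pesa is not None:
                feats = pesa(feats, Tensor(np.swapaxes(coords, 1, 2)
                                           .astype(np.float32)))
            skip_feats.append(feats)
            skip_coords.append(coords)
        # decode from the bottleneck back to full resolution
        for s, fp in enumerate(self.fp_stages):
            level = len(skip_feats) - 2 - s
            feats = fp(feats, skip_coords[level + 1], skip_coords[level],
                       skip_feats[level])
        feats = self.head_dropout(self.head_bn(self.head_hidden(feats)).relu())
        logits = self.head(feats).swapaxes(1, 2)     # (B, N, num_classes)
        if return_logits:
            return logits
        return logits.softmax(axis=2)

    def predict(self, points: np.ndarray) -> np.ndarray:
        """Evaluation-mode hard labels for one (N, 3) cloud or a (B, N, 3) batch."""
        was_single = np.asarray(points).ndim == 2
        self.eval()
        with no_grad():
            probs = self.forward(points)
        labels = probs.data.argmax(axis=2)
        return labels[0] if was_single else labels
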