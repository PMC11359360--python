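"""Cloud preprocessing: statistical outlier removal, normalization,
fixed-size resampling, and the three-way augmentation scheme.

The statistical filter scores each point by its mean distance to its k nearest
neighbors and discards points whose score exceeds the global mean by more than
``std_ratio`` standard deviations — the classic PCL-style statistical outlier
removal. Augmentation expands each original cloud into four entries: itself,
a random rotation about the vertical axis, a clipped Gaussian jitter, and an
unclipped Gaussian noise variant.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .datasets import DatasetManifest
from .io import LabeledCloud, read_cloud, write_cloud

__all__ = [
    "FilterParams", "AugmentParams", "TransformRecord",
    "statistical_outlier_removal", "normalize", "resample_fixed",
    "augment_rotation", "augment_jitter", "augment_noise", "build_augmented",
]


@dataclass
class FilterParams:
    """k-NN statistical filter parameters. Defaults: k=16, std_ratio=2."""

    k_neighbors: int = 16
    std_ratio: float = 2.0

    def __post_init__(self):
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.std_ratio <= 0:
            raise ValueError("std_ratio must be positive")


@dataclass
class AugmentParams:
    """Vertical-axis rotation; clipped jitter; unclipped Gaussian noise.

    Sigmas are in normalized units (unit-sphere scale). Jitter is clipped per
    coordinate at ``jitter_clip``; the Gaussian-noise variant is unclipped —
    that absence of clipping is what distinguishes the two augmentations.
    """

    jitter_sigma: float = 0.01
    jitter_clip: float = 0.05
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if min(self.jitter_sigma, self.noise_sigma) < 0:
            raise ValueError("sigmas must be nonnegative")
        if self.jitter_clip < self.jitter_sigma:
            raise ValueError("jitter_clip must be >= jitter_sigma")


def statistical_outlier_removal(cloud: LabeledCloud, params: FilterParams
                                ) -> tuple[LabeledCloud, np.ndarray]:
    """Remove points whose mean k-NN distance exceeds mean + std_ratio * std.

    Returns the kept cloud (labels carried through) and the removed indices.
    """
    m = len(cloud)
    if m <= params.k_neighbors:
        raise ValueError(
            f"cloud has {m} points but k_neighbors={params.k_neighbors} requires more")
    tree = cKDTree(cloud.points)
    # k+1 because the closest neighbor of each point is itself
    dists, _ = tree.query(cloud.points, k=params.k_neighbors + 1)
    mean_d = dists[:, 1:].mean(axis=1)
    threshold = mean_d.mean() + params.std_ratio * mean_d.std()
    keep = mean_d <= threshold
    removed = np.flatnonzero(~keep)
    kept = LabeledCloud(
        cloud.points[keep],
        cloud.labels[keep] if cloud.has_labels else None,
        cloud.origin_id, cloud.variant)
    return kept, removed


@dataclass
class TransformRecord:
    """Invertible record of the centering/scaling applied by :func:`normalize`."""

    centroid: np.ndarray
    scale: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return (points - self.centroid) / self.scale

    def invert(self, points: np.ndarray) -> np.ndarray:
        return points * self.scale + self.centroid


def normalize(cloud: LabeledCloud) -> tuple[LabeledCloud, TransformRecord]:
    """Center at the centroid and scale the max radius to 1."""
    centroid = cloud.points.mean(axis=0)
    radius = np.linalg.norm(cloud.points - centroid, axis=1).max()
    scale = radius if radius > 0 else 1.0
    rec = TransformRecord(centroid=centroid, scale=scale)
    return cloud.with_points(rec.apply(cloud.points)), rec


def resample_fixed(cloud: LabeledCloud, n_points: int, seed: int = 0) -> LabeledCloud:
    """Resample to exactly `n_points`: farthest-point subsample when the cloud
    is larger, uniform sampling with replacement of extra indices when smaller."""
    from .backbone import farthest_point_sample  # local import; no cycle at runtime

    m = len(cloud)
    rng = np.random.default_rng(seed)
    if m >= n_points:
        start = int(rng.integers(m))
        idx = farthest_point_sample(cloud.points, n_points, start_index=start)
    else:
        extra = rng.integers(0, m, size=n_points - m)
        idx = np.concatenate([np.arange(m), extra])
    return LabeledCloud(
        cloud.points[idx],
        cloud.labels[idx] if cloud.has_labels else None,
        cloud.origin_id, cloud.variant)


def augment_rotation(cloud: LabeledCloud, rng: np.random.Generator,
                     angle: float | None = None) -> LabeledCloud:
    """Rotate by one angle ~ U[0, 2pi) about the vertical axis through the centroid."""
    theta = rng.uniform(0, 2 * np.pi) if angle is None else angle
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    centroid = cloud.points.mean(axis=0)
    pts = (cloud.points - centroid) @ rot.T + centroid
    return cloud.with_points(pts, variant="rotated")


def augment_jitter(cloud: LabeledCloud, params: AugmentParams,
                   rng: np.random.Generator) -> LabeledCloud:
    """Per-point i.i.d. Gaussian offsets, clipped per coordinate."""
    offset = rng.normal(0, params.jitter_sigma, cloud.points.shape) \
        if params.jitter_sigma > 0 else np.zeros_like(cloud.points)
    offset = np.clip(offset, -params.jitter_clip, params.jitter_clip)
    return cloud.with_points(cloud.points + offset, variant="jittered")


def augment_noise(cloud: LabeledCloud, params: AugmentParams,
                  rng: np.random.Generator) -> LabeledCloud:
    """Unclipped additive Gaussian perturbation."""
    offset = rng.normal(0, params.noise_sigma, cloud.points.shape) \
        if params.noise_sigma > 0 else np.zeros_like(cloud.points)
    return cloud.with_points(cloud.points + offset, variant="noised")


def build_augmented(manifest: DatasetManifest, params: AugmentParams,
                    out_dir: str | None = None) -> DatasetManifest:
    """Expand every original entry into 4: itself + rotated + jittered + noised.

    New variant files are written next to the originals (or under `out_dir`);
    the returned manifest holds 4 x #originals entries.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    for _, row in manifest.entries.iterrows():
        if row["variant"] != "original":
            continue
        rows.append(dict(row))
        cloud = read_cloud(row["path"])
        base_dir = out_dir or os.path.dirname(row["path"])
        os.makedirs(base_dir, exist_ok=True)
        stem_name, ext = os.path.splitext(os.path.basename(row["path"]))
        for variant, fn in (("rotated", augment_rotation),
                            ("jittered", lambda c, r: augment_jitter(c, params, r)),
                            ("noised", lambda c, r: augment_noise(c, params, r))):
            new = fn(cloud, rng)
            path = os.path.join(base_dir, f"{stem_name}_{variant}{ext}")
            write_cloud(new, path)
            rows.append({"path": path, "origin_id": row["origin_id"],
                         "variant": variant, "split": row["split"]})
    return DatasetManifest(pd.DataFrame(rows))
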