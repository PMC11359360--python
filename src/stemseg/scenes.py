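"""Synthetic seedling-scene generator.

Builds labeled point clouds that mimic the structure of scanned cucurbit
seedlings in pots: a curved stem (label 1 = stem) rising from potting soil,
drooping leaves attached at the apex via short petioles, optional pot shell,
wall and table planes, and uniform outlier noise (all label 0 = other).

The generator's role is to provide controllable stand-ins for the four scene
families a stem-segmentation model must cope with: multi-branch plants, extra
pots/clutter, heavy noise with background planes, and two-plant scenes. Scenes
are generated in a z-up frame with the soil surface at z = 0 and stem lengths
of roughly 0.1-0.5 scene units; the stem base is embedded slightly below the
soil so the stem/soil boundary is genuinely ambiguous, as it is in real scans.

Everything is deterministic given ``SceneSpec.seed``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datasets import DatasetManifest
from .io import LabeledCloud, write_cloud

__all__ = ["SceneSpec", "SceneBundle", "generate_seedling", "generate_scene",
           "generate_dataset", "PRESETS", "preset_spec", "default_spec_sampler"]

POT_RADIUS = 0.07
POT_DEPTH = 0.08
SOIL_EMBED = 0.02  # how far the stem base sits below the soil surface


@dataclass
class SceneSpec:
    """Parametric description of one synthetic seedling scene."""

    stem_length: float = 0.35
    stem_radius: float = 0.008
    curvature: float = 0.06      # lateral amplitude of the stem spine
    branches: int = 0            # petiole-like side tubes (labeled other)
    leaf_count: int = 2
    leaf_radius: float = 0.08
    leaf_droop_deg: float = 35.0
    soil: bool = True
    pot: bool = True
    wall: bool = False
    table: bool = False
    wall_density: float = 0.15   # area weight multiplier for background planes
    outlier_rate: float = 0.02
    points_total: int = 4096
    plants: int = 1
    seed: int = 0

    def validate(self):
        if self.points_total < 256:
            raise ValueError("points_total must be >= 256")
        if not 0.0 <= self.outlier_rate <= 0.2:
            raise ValueError("outlier_rate must lie in [0, 0.2]")
        if self.stem_radius <= 0:
            raise ValueError("stem_radius must be positive")
        if self.plants < 1:
            raise ValueError("plants must be >= 1")
        if min(self.stem_length, self.leaf_radius) <= 0:
            raise ValueError("lengths must be positive")


@dataclass
class SceneBundle:
    """A generated cloud with its spec and ground-truth part masks."""

    cloud: LabeledCloud
    spec: SceneSpec
    truth_masks: dict[str, np.ndarray]


# --------------------------------------------------------------------------
# geometry helpers


def _spine(rng: np.random.Generator, spec: SceneSpec, base: np.ndarray):
    """Cubic-polynomial stem spine from below the soil to the apex."""
    embed = SOIL_EMBED if spec.soil else 0.0
    length = spec.stem_length + embed
    cx = rng.uniform(-1, 1, 3) * spec.curvature
    cy = rng.uniform(-1, 1, 3) * spec.curvature

    def f(t):
        t = np.asarray(t, dtype=float)
        lateral_x = cx[0] * t + cx[1] * t**2 + cx[2] * t**3
        lateral_y = cy[0] * t + cy[1] * t**2 + cy[2] * t**3
        return np.stack([base[0] + lateral_x, base[1] + lateral_y,
                         base[2] - embed + t * length], axis=-1)

    return f


def _tube_points(rng, f, radius, n):
    """Sample n points on the tube of radius `radius` around spine f."""
    t = rng.uniform(0, 1, n)
    theta = rng.uniform(0, 2 * np.pi, n)
    centers = f(t)
    eps = 1e-4
    tangents = f(np.minimum(t + eps, 1.0)) - f(np.maximum(t - eps, 0.0))
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    ref = np.tile(np.array([1.0, 0.0, 0.0]), (n, 1))
    ref[np.abs(tangents[:, 0]) > 0.9] = [0.0, 1.0, 0.0]
    n1 = np.cross(tangents, ref)
    n1 /= np.linalg.norm(n1, axis=1, keepdims=True)
    n2 = np.cross(tangents, n1)
    offset = radius * (np.cos(theta)[:, None] * n1 + np.sin(theta)[:, None] * n2)
    return centers + offset


def _leaf_points(rng, attach, droop_deg, leaf_radius, n):
    """Drooping elliptical patch with a slight parabolic sag."""
    azimuth = rng.uniform(0, 2 * np.pi)
    droop = np.deg2rad(droop_deg + rng.uniform(-5, 5))
    r = np.sqrt(rng.uniform(0, 1, n))
    phi = rng.uniform(0, 2 * np.pi, n)
    u = r * np.cos(phi) * leaf_radius
    v = r * np.sin(phi) * 0.6 * leaf_radius
    sag = -0.35 * (u**2 + v**2) / leaf_radius  # curls downward away from center
    local = np.stack([u + leaf_radius, v, sag], axis=-1)  # petiole end at origin
    cd, sd = np.cos(droop), np.sin(droop)
    tilt = np.array([[cd, 0, -sd], [0, 1, 0], [sd, 0, cd]])
    ca, sa = np.cos(azimuth), np.sin(azimuth)
    rot = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
    return (rot @ tilt @ local.T).T + attach


def _disk_points(rng, center, radius, n, rough=0.002):
    r = radius * np.sqrt(rng.uniform(0, 1, n))
    phi = rng.uniform(0, 2 * np.pi, n)
    z = center[2] + rng.normal(0, rough, n)
    return np.stack([center[0] + r * np.cos(phi), center[1] + r * np.sin(phi), z],
                    axis=-1)


def _cylinder_points(rng, center, radius, z_lo, z_hi, n):
    phi = rng.uniform(0, 2 * np.pi, n)
    z = rng.uniform(z_lo, z_hi, n)
    return np.stack([center[0] + radius * np.cos(phi),
                     center[1] + radius * np.sin(phi), z], axis=-1)


def _plane_points(rng, origin, axis_u, axis_v, extent_u, extent_v, n):
    u = rng.uniform(-extent_u / 2, extent_u / 2, n)
    v = rng.uniform(0, extent_v, n)
    return origin + u[:, None] * axis_u + v[:, None] * axis_v


def _allocate(weights: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder integer allocation proportional to `weights`."""
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0 or total <= 0:
        return np.zeros(len(weights), dtype=int)
    exact = weights / weights.sum() * total
    counts = np.floor(exact).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(exact - counts))
    counts[order[:short]] += 1
    return counts


# --------------------------------------------------------------------------
# generation


def _generate(spec: SceneSpec, include_clutter: bool) -> SceneBundle:
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_outliers = int(round(spec.outlier_rate * spec.points_total)) if include_clutter else 0
    n_surface = spec.points_total - n_outliers

    # pot centers on a line, spaced so pots never overlap
    spacing = 2.5 * 2 * POT_RADIUS
    centers = [np.array([i * spacing, 0.0, 0.0]) for i in range(spec.plants)]

    surfaces = []  # (mask_name, label, area_weight, sampler)
    for center in centers:
        f = _spine(rng, spec, center)
        stem_area = 2 * np.pi * spec.stem_radius * spec.stem_length
        surfaces.append(("stem", 1, stem_area,
                         lambda n, f=f: _tube_points(rng, f, spec.stem_radius, n)))
        apex = f(1.0)
        attach_pts = [apex]
        for _ in range(spec.branches):
            t0 = rng.uniform(0.45, 0.9)
            start = f(t0)
            direction = np.array([rng.uniform(-1, 1), rng.uniform(-1, 1),
                                  rng.uniform(0.4, 1.0)])
            direction /= np.linalg.norm(direction)
            blen = 0.4 * spec.stem_length
            end = start + direction * blen

            def bf(t, s=start, e=end):
                t = np.asarray(t, dtype=float)[..., None]
                return s + t * (e - s)

            barea = 2 * np.pi * 0.7 * spec.stem_radius * blen
            surfaces.append(("leaf", 0, barea,
                             lambda n, bf=bf: _tube_points(
                                 rng, bf, 0.7 * spec.stem_radius, n)))
            attach_pts.append(end)
        for li in range(spec.leaf_count):
            attach = attach_pts[li % len(attach_pts)]
            larea = np.pi * spec.leaf_radius * 0.6 * spec.leaf_radius
            surfaces.append(("leaf", 0, larea,
                             lambda n, a=attach: _leaf_points(
                                 rng, a, spec.leaf_droop_deg, spec.leaf_radius, n)))
        if include_clutter and spec.soil:
            surfaces.append(("soil", 0, np.pi * POT_RADIUS**2,
                             lambda n, c=center: _disk_points(rng, c, POT_RADIUS, n)))
        if include_clutter and spec.pot:
            surfaces.append(("pot", 0, 2 * np.pi * POT_RADIUS * POT_DEPTH,
                             lambda n, c=center: _cylinder_points(
                                 rng, c, POT_RADIUS, -POT_DEPTH, 0.0, n)))
    if include_clutter and spec.wall:
        origin = np.array([0.0, 0.45, -POT_DEPTH])
        surfaces.append(("wall", 0, 0.6 * 0.6 * spec.wall_density,
                         lambda n: _plane_points(rng, origin, np.array([1.0, 0, 0]),
                                                 np.array([0, 0, 1.0]), 0.6, 0.6, n)))
    if include_clutter and spec.table:
        origin = np.array([0.0, 0.0, -POT_DEPTH])
        surfaces.append(("table", 0, 0.5 * 0.5 * spec.wall_density,
                         lambda n: _plane_points(rng, origin, np.array([1.0, 0, 0]),
                                                 np.array([0, 1.0, 0]), 0.8, 0.4, n)
                         - np.array([0.0, 0.2, 0.0])))

    counts = _allocate(np.array([s[2] for s in surfaces]), n_surface)
    # every surface contributes at least one point (steal from the largest)
    for i in range(len(counts)):
        if counts[i] == 0:
            counts[np.argmax(counts)] -= 1
            counts[i] = 1

    pts, labels, names = [], [], []
    for (name, label, _w, sampler), cnt in zip(surfaces, counts):
        if cnt <= 0:
            continue
        p = sampler(cnt)
        pts.append(p)
        labels.append(np.full(cnt, label, dtype=np.int64))
        names.extend([name] * cnt)
    points = np.vstack(pts)
    labels = np.concatenate(labels)

    if n_outliers:
        lo, hi = points.min(axis=0), points.max(axis=0)
        mid, half = (lo + hi) / 2, (hi - lo) / 2
        lo_i, hi_i = mid - 1.5 * half, mid + 1.5 * half
        out = rng.uniform(lo_i, hi_i, (n_outliers, 3))
        points = np.vstack([points, out])
        labels = np.concatenate([labels, np.zeros(n_outliers, dtype=np.int64)])
        names.extend(["outlier"] * n_outliers)

    masks = {}
    names_arr = np.array(names)
    for name in ("stem", "leaf", "soil", "pot", "wall", "table", "outlier"):
        idx = np.flatnonzero(names_arr == name)
        if idx.size:
            masks[name] = idx
    cloud = LabeledCloud(points, labels, origin_id=f"scene_{spec.seed}")
    return SceneBundle(cloud=cloud, spec=spec, truth_masks=masks)


def generate_seedling(spec: SceneSpec) -> SceneBundle:
    """Plant only (stem + petioles + leaves), no clutter, no outliers."""
    return _generate(spec, include_clutter=False)


def generate_scene(spec: SceneSpec) -> SceneBundle:
    """Full scene: plant(s) plus soil/pot/wall/table clutter and outliers."""
    return _generate(spec, include_clutter=True)


# --------------------------------------------------------------------------
# presets and dataset generation

PRESETS = {
    "simple": dict(),
    "branchy": dict(branches=3, leaf_count=4),
    "cluttered": dict(wall=True, table=True, outlier_rate=0.06),
    "two-plant": dict(plants=2, leaf_count=3),
    "early": dict(stem_length=0.07, stem_radius=0.004, leaf_count=1,
                  leaf_radius=0.05, curvature=0.01),
}


def preset_spec(name: str, **overrides) -> SceneSpec:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    params = dict(PRESETS[name])
    params.update(overrides)
    return SceneSpec(**params)


def default_spec_sampler(rng: np.random.Generator) -> SceneSpec:
    """Random spec spanning the four scene families plus simple seedlings."""
    name = rng.choice(["simple", "simple", "branchy", "cluttered", "two-plant", "early"])
    spec = preset_spec(str(name))
    return replace(
        spec,
        stem_length=spec.stem_length * rng.uniform(0.7, 1.3),
        stem_radius=spec.stem_radius * rng.uniform(0.8, 1.25),
        curvature=spec.curvature * rng.uniform(0.5, 1.5),
        leaf_droop_deg=spec.leaf_droop_deg + rng.uniform(-10, 10),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_dataset(n_origins: int, out_dir: str, seed: int = 0,
                     spec_sampler=None, points_total: int = 4096,
                     fmt: str = "ply") -> DatasetManifest:
    """Generate `n_origins` scenes, write them and return a manifest."""
    if n_origins < 1:
        raise ValueError("n_origins must be >= 1")
    sampler = spec_sampler or default_spec_sampler
    rng = np.random.default_rng(seed)
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i in range(n_origins):
        spec = sampler(rng)
        spec = replace(spec, points_total=points_total)
        bundle = generate_scene(spec)
        origin = f"scene_{i:04d}"
        bundle.cloud.origin_id = origin
        path = os.path.join(out_dir, f"{origin}.{fmt}")
        write_cloud(bundle.cloud, path, format=fmt)
        rows.append({"path": path, "origin_id": origin,
                     "variant": "original", "split": "none"})
    manifest = DatasetManifest(pd.DataFrame(rows))
    manifest.save(os.path.join(out_dir, "manifest.tsv"))
    return manifest
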