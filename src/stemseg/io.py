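"""Labeled point-cloud container and ASCII file I/O.

Supported formats, all plain text:

* **PLY** (ASCII 1.0) with vertex properties ``x y z`` plus optional ``label``
  and optional ``red green blue``.
* **PCD** v0.7 ASCII with ``FIELDS x y z [label]``.
* **xyzl** — whitespace-separated rows of ``x y z [label]``.

Class semantics are fixed package-wide: label 0 = "other", 1 = "stem". When a
cloud is written with ``colorize=True`` the stem is green and everything else
blue, the convention used for visualizing stem segmentations.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["LabeledCloud", "read_cloud", "write_cloud", "CLASS_NAMES",
           "STEM_COLOR", "OTHER_COLOR", "CloudFormatError"]

CLASS_NAMES = ("other", "stem")
STEM_COLOR = (0, 255, 0)
OTHER_COLOR = (0, 0, 255)

VARIANTS = ("original", "rotated", "jittered", "noised")


class CloudFormatError(ValueError):
    """Raised for malformed or unsupported point-cloud files."""


@dataclass
class LabeledCloud:
    """XYZ points with optional per-point binary class labels.

    Attributes
    ----------
    points : (M, 3) float64 array
        Coordinates in arbitrary raw units.
    labels : (M,) int array or None
        0 = other, 1 = stem. ``None`` for unlabeled clouds.
    origin_id : str
        Identifier of the source specimen.
    variant : str
        One of ``original | rotated | jittered | noised``.
    """

    points: np.ndarray
    labels: Optional[np.ndarray] = None
    origin_id: str = ""
    variant: str = "original"

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must be (M, 3), got {self.points.shape}")
        if len(self.points) < 1:
            raise ValueError("cloud must contain at least one point")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (len(self.points),):
                raise ValueError("labels length must match point count")
            if not np.isin(self.labels, (0, 1)).all():
                raise ValueError("labels must be 0 (other) or 1 (stem)")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def has_labels(self) -> bool:
        return self.labels is not None

    def with_points(self, points: np.ndarray, variant: str | None = None) -> "LabeledCloud":
        return LabeledCloud(points, None if self.labels is None else self.labels.copy(),
                            self.origin_id, variant or self.variant)


def _infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext in ("ply", "pcd"):
        return ext
    if ext in ("xyzl", "xyz", "txt"):
        return "xyzl"
    raise CloudFormatError(f"cannot infer format from extension {ext!r} of {path}")


def read_cloud(path: str, format: str = "auto") -> LabeledCloud:
    """Read a cloud; the label column becomes {0,1} labels when present."""
    fmt = _infer_format(path) if format == "auto" else format
    if fmt == "ply":
        cloud = _read_ply(path)
    elif fmt == "pcd":
        cloud = _read_pcd(path)
    elif fmt == "xyzl":
        cloud = _read_xyzl(path)
    else:
        raise CloudFormatError(f"unsupported format {fmt!r}")
    cloud.origin_id = os.path.splitext(os.path.basename(path))[0]
    return cloud


def write_cloud(cloud: LabeledCloud, path: str, format: str = "auto",
                colorize: bool = False) -> None:
    """Write a cloud. ``colorize`` adds green/blue RGB for stem/other."""
    if colorize and not cloud.has_labels:
        raise ValueError("colorize requires labels")
    fmt = _infer_format(path) if format == "auto" else format
    if fmt == "ply":
        _write_ply(cloud, path, colorize)
    elif fmt == "pcd":
        _write_pcd(cloud, path)
    elif fmt == "xyzl":
        _write_xyzl(cloud, path)
    else:
        raise CloudFormatError(f"unsupported format {fmt!r}")


# --------------------------------------------------------------------------
# xyzl


def _read_xyzl(path: str) -> LabeledCloud:
    pts, labels = [], []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if ncols is None:
                if len(parts) not in (3, 4):
                    raise CloudFormatError(
                        f"{path}:{lineno}: expected 3 or 4 columns, got {len(parts)}")
                ncols = len(parts)
            if len(parts) != ncols:
                raise CloudFormatError(
                    f"{path}:{lineno}: inconsistent column count {len(parts)}")
            try:
                pts.append([float(v) for v in parts[:3]])
                if ncols == 4:
                    labels.append(int(float(parts[3])))
            except ValueError as exc:
                raise CloudFormatError(f"{path}:{lineno}: {exc}") from None
    if not pts:
        raise CloudFormatError(f"{path}: no points")
    return LabeledCloud(np.array(pts), np.array(labels) if labels else None)


def _write_xyzl(cloud: LabeledCloud, path: str) -> None:
    with open(path, "w") as fh:
        for i, (x, y, z) in enumerate(cloud.points):
            if cloud.has_labels:
                fh.write(f"{x:.12g} {y:.12g} {z:.12g} {cloud.labels[i]}\n")
            else:
                fh.write(f"{x:.12g} {y:.12g} {z:.12g}\n")


# --------------------------------------------------------------------------
# PLY (ASCII)


def _read_ply(path: str) -> LabeledCloud:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise CloudFormatError(f"{path}: not a PLY file")
    n_vertex = None
    props: list[str] = []
    i = 1
    in_vertex = False
    while i < len(lines):
        tok = lines[i].split()
        if not tok:
            i += 1
            continue
        if tok[0] == "format":
            if tok[1] != "ascii":
                raise CloudFormatError(f"{path}: only ASCII PLY is supported")
        elif tok[0] == "element":
            in_vertex = tok[1] == "vertex"
            if in_vertex:
                n_vertex = int(tok[2])
        elif tok[0] == "property" and in_vertex:
            props.append(tok[-1])
        elif tok[0] == "end_header":
            i += 1
            break
        i += 1
    if n_vertex is None:
        raise CloudFormatError(f"{path}: no vertex element")
    for needed in ("x", "y", "z"):
        if needed not in props:
            raise CloudFormatError(f"{path}: vertex property {needed!r} missing")
    rows = []
    for lineno in range(i, i + n_vertex):
        if lineno >= len(lines):
            raise CloudFormatError(f"{path}: expected {n_vertex} vertices, file ended")
        parts = lines[lineno].split()
        if len(parts) != len(props):
            raise CloudFormatError(
                f"{path}:{lineno + 1}: expected {len(props)} values, got {len(parts)}")
        try:
            rows.append([float(v) for v in parts])
        except ValueError as exc:
            raise CloudFormatError(f"{path}:{lineno + 1}: {exc}") from None
    data = np.array(rows)
    cols = {p: data[:, j] for j, p in enumerate(props)}
    pts = np.column_stack([cols["x"], cols["y"], cols["z"]])
    labels = cols["label"].astype(np.int64) if "label" in cols else None
    return LabeledCloud(pts, labels)


def _write_ply(cloud: LabeledCloud, path: str, colorize: bool) -> None:
    header = ["ply", "format ascii 1.0",
              f"element vertex {len(cloud)}",
              "property float64 x", "property float64 y", "property float64 z"]
    if cloud.has_labels:
        header.append("property int label")
    if colorize:
        header += ["property uchar red", "property uchar green", "property uchar blue"]
    header.append("end_header")
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        for i, (x, y, z) in enumerate(cloud.points):
            row = f"{x:.12g} {y:.12g} {z:.12g}"
            if cloud.has_labels:
                row += f" {cloud.labels[i]}"
            if colorize:
                r, g, b = STEM_COLOR if cloud.labels[i] == 1 else OTHER_COLOR
                row += f" {r} {g} {b}"
            fh.write(row + "\n")


# --------------------------------------------------------------------------
# PCD v0.7 (ASCII)


def _read_pcd(path: str) -> LabeledCloud:
    with open(path) as fh:
        lines = fh.read().splitlines()
    fields = None
    n_points = None
    data_start = None
    for i, line in enumerate(lines):
        tok = line.split()
        if not tok or tok[0].startswith("#"):
            continue
        if tok[0] == "FIELDS":
            fields = tok[1:]
        elif tok[0] == "POINTS":
            n_points = int(tok[1])
        elif tok[0] == "DATA":
            if tok[1] != "ascii":
                raise CloudFormatError(f"{path}: only ASCII PCD is supported")
            data_start = i + 1
            break
    if fields is None or n_points is None or data_start is None:
        raise CloudFormatError(f"{path}: incomplete PCD header")
    rows = []
    for lineno in range(data_start, data_start + n_points):
        parts = lines[lineno].split()
        if len(parts) != len(fields):
            raise CloudFormatError(
                f"{path}:{lineno + 1}: expected {len(fields)} values, got {len(parts)}")
        rows.append([float(v) for v in parts])
    data = np.array(rows)
    cols = {f: data[:, j] for j, f in enumerate(fields)}
    pts = np.column_stack([cols["x"], cols["y"], cols["z"]])
    labels = cols["label"].astype(np.int64) if "label" in cols else None
    return LabeledCloud(pts, labels)


def _write_pcd(cloud: LabeledCloud, path: str) -> None:
    fields = "x y z label" if cloud.has_labels else "x y z"
    n = len(cloud)
    nf = 4 if cloud.has_labels else 3
    header = [
        "# .PCD v0.7 - Point Cloud Data file format",
        "VERSION 0.7",
        f"FIELDS {fields}",
        "SIZE " + " ".join(["8"] * nf),
        "TYPE " + " ".join(["F"] * 3 + (["I"] if cloud.has_labels else [])),
        "COUNT " + " ".join(["1"] * nf),
        f"WIDTH {n}", "HEIGHT 1",
        "VIEWPOINT 0 0 0 1 0 0 0",
        f"POINTS {n}", "DATA ascii",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        for i, (x, y, z) in enumerate(cloud.points):
            if cloud.has_labels:
                fh.write(f"{x:.12g} {y:.12g} {z:.12g} {cloud.labels[i]}\n")
            else:
                fh.write(f"{x:.12g} {y:.12g} {z:.12g}\n")
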