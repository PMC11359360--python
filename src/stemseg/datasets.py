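"""Dataset manifests and specimen-grouped train/test and k-fold splitting.

A manifest is a table of (path, origin_id, variant, split). Splits are always
grouped by ``origin_id`` so that augmented variants of one specimen never leak
across the train/test boundary. A "4:1" ratio resolves to a train fraction of
0.8 applied with ``floor`` to the *origin* count: 298 specimens with their 4
variants split 4:1 this way yields the 952-train / 240-test partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DatasetManifest", "SplitResult", "split_grouped", "kfold_grouped",
           "parse_ratio"]

MANIFEST_COLUMNS = ["path", "origin_id", "variant", "split"]


@dataclass
class DatasetManifest:
    """Table of dataset entries plus the fixed class ordering."""

    entries: pd.DataFrame
    class_names: tuple = ("other", "stem")

    def __post_init__(self):
        df = pd.DataFrame(self.entries)
        for col in MANIFEST_COLUMNS:
            if col not in df.columns:
                df[col] = "" if col != "split" else "none"
        self.entries = df[MANIFEST_COLUMNS].reset_index(drop=True)
        if (self.entries["origin_id"] == "").any():
            raise ValueError("every entry needs a non-empty origin_id")
        dup = self.entries.duplicated(subset=["origin_id", "variant"])
        if dup.any():
            raise ValueError(
                f"duplicate (origin_id, variant) pairs: "
                f"{self.entries[dup][['origin_id', 'variant']].values.tolist()}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def origin_ids(self) -> list[str]:
        return list(dict.fromkeys(self.entries["origin_id"]))

    def save(self, path: str) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path: str) -> "DatasetManifest":
        return cls(pd.read_csv(path, sep="\t", dtype=str))


@dataclass
class SplitResult:
    """Row indices of the manifest assigned to each side."""

    train: np.ndarray
    test: np.ndarray
    ratio: float

    def __post_init__(self):
        if np.intersect1d(self.train, self.test).size:
            raise ValueError("train and test overlap")


def parse_ratio(ratio) -> float:
    """Resolve a ratio to a train fraction: '4:1' -> 0.8, 0.8 -> 0.8."""
    if isinstance(ratio, str) and ":" in ratio:
        a, b = (float(v) for v in ratio.split(":"))
        return a / (a + b)
    r = float(ratio)
    if not 0.0 < r < 1.0:
        raise ValueError(f"train fraction must be in (0, 1), got {r}")
    return r


def split_grouped(manifest: DatasetManifest, ratio="4:1",
                  seed: int = 0) -> SplitResult:
    """Shuffle origins by seed; floor(frac * #origins) go to train, rest to test.

    All variants of one origin land on the same side.
    """
    frac = parse_ratio(ratio)
    origins = np.array(manifest.origin_ids)
    if len(origins) < 2:
        raise ValueError("need at least 2 origins to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(origins))
    n_train = int(np.floor(frac * len(origins)))
    train_origins = set(origins[order[:n_train]])
    member = manifest.entries["origin_id"].isin(train_origins).to_numpy()
    return SplitResult(train=np.flatnonzero(member),
                       test=np.flatnonzero(~member), ratio=frac)


def kfold_grouped(manifest: DatasetManifest, k: int, seed: int = 0) -> list[SplitResult]:
    """k folds grouped by origin; validation-fold sizes differ by at most one origin."""
    origins = np.array(manifest.origin_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(origins):
        raise ValueError(f"k={k} exceeds the {len(origins)} available origins")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(origins))
    fold_assign = np.empty(len(origins), dtype=int)
    # near-equal partition: the first (n % k) folds get one extra origin
    sizes = np.full(k, len(origins) // k)
    sizes[: len(origins) % k] += 1
    start = 0
    for f, s in enumerate(sizes):
        fold_assign[order[start:start + s]] = f
        start += s
    origin_fold = dict(zip(origins, fold_assign))
    entry_fold = manifest.entries["origin_id"].map(origin_fold).to_numpy()
    results = []
    for f in range(k):
        val = np.flatnonzero(entry_fold == f)
        train = np.flatnonzero(entry_fold != f)
        results.append(SplitResult(train=train, test=val, ratio=1.0 - 1.0 / k))
    return results
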