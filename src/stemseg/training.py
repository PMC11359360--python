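"""Seeded training loop: Adam with cosine learning-rate decay, switchable
hybrid loss, checkpointing, and grouped k-fold cross-validation.

The learning rate decays along a half cosine from ``lr_init`` at epoch 0 to
``lr_min`` at the final epoch. Point order within each cloud is reshuffled
every epoch, which also randomizes the farthest-point-sampling start point
during training; evaluation is deterministic.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from .autograd import no_grad
from .backbone import StemSegNet
from .config import LossConfig, ModelConfig, TrainConfig
from .datasets import DatasetManifest, kfold_grouped
from .io import LabeledCloud, read_cloud
from .losses import make_loss
from .metrics import EvalCounts, MetricReport, confusion, report
from .nn import Adam
from .preprocess import normalize, resample_fixed

__all__ = ["lr_schedule", "train", "evaluate", "cross_validate",
           "TrainHistory", "save_checkpoint", "load_checkpoint",
           "prepare_clouds"]


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Cosine decay from lr_init (epoch 0) to lr_min (final epoch)."""
    if not 0 <= epoch < config.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs})")
    if config.epochs == 1:
        return config.lr_init
    t = epoch / (config.epochs - 1)
    return config.lr_min + 0.5 * (config.lr_init - config.lr_min) * (
        1.0 + np.cos(np.pi * t))


@dataclass
class TrainHistory:
    """Per-epoch records of the run."""

    epochs: list = field(default_factory=list)

    def append(self, **kwargs):
        self.epochs.append(kwargs)

    def __len__(self):
        return len(self.epochs)

    def series(self, key: str) -> list:
        return [e.get(key) for e in self.epochs]


def prepare_clouds(clouds: list[LabeledCloud], n_points: int, seed: int = 0
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Normalize and resample labeled clouds to fixed-size training arrays."""
    xs, ys = [], []
    rng = np.random.default_rng(seed)
    for cloud in clouds:
        if not cloud.has_labels:
            raise ValueError(f"cloud {cloud.origin_id!r} has no labels")
        normed, _ = normalize(cloud)
        fixed = resample_fixed(normed, n_points, seed=int(rng.integers(2**31 - 1)))
        xs.append(fixed.points.astype(np.float32))
        ys.append(fixed.labels)
    return np.stack(xs), np.stack(ys)


def evaluate(model: StemSegNet, x: np.ndarray, y: np.ndarray,
             loss_fn=None, batch_size: int = 6
             ) -> tuple[MetricReport, EvalCounts, float | None]:
    """Deterministic evaluation: pooled confusion counts over all clouds."""
    model.eval()
    counts = EvalCounts.zeros(model.config.num_classes)
    losses = []
    t0 = time.perf_counter()
    with no_grad():
        for i in range(0, len(x), batch_size):
            xb, yb = x[i:i + batch_size], y[i:i + batch_size]
            probs = model.forward(xb)
            pred = probs.data.argmax(axis=2)
            counts = counts + confusion(pred, yb, model.config.num_classes)
            if loss_fn is not None:
                losses.append(loss_fn(probs, yb).item())
    elapsed = time.perf_counter() - t0
    rep = report(counts, total_time=elapsed, n_clouds=len(x))
    return rep, counts, (float(np.mean(losses)) if losses else None)


def train(model: StemSegNet, x: np.ndarray, y: np.ndarray,
          train_config: TrainConfig, loss_config: LossConfig,
          x_val: np.ndarray | None = None, y_val: np.ndarray | None = None,
          log=None) -> TrainHistory:
    """Train in place; returns the per-epoch history.

    x: (n, N, 3) normalized coordinates, y: (n, N) labels in {0, 1}.
    Aborts if the training labels contain a single class.
    """
    train_config.validate()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(
            f"training data contains a single class {classes.tolist()}; "
            "both stem and other points are required")
    loss_fn = make_loss(loss_config)
    rng = np.random.default_rng(train_config.seed)
    optimizer = Adam(model.parameters(), lr=train_config.lr_init,
                     beta1=train_config.momentum)
    history = TrainHistory()
    n = len(x)
    for epoch in range(train_config.epochs):
        lr = lr_schedule(epoch, train_config)
        optimizer.lr = lr
        model.train()
        order = rng.permutation(n)
        epoch_losses = []
        for i in range(0, n, train_config.batch_size):
            sel = order[i:i + train_config.batch_size]
            xb = x[sel].copy()
            yb = y[sel].copy()
            for j in range(len(sel)):  # reshuffle point order (FPS start diversity)
                perm = rng.permutation(xb.shape[1])
                xb[j] = xb[j][perm]
                yb[j] = yb[j][perm]
                if train_config.rotate_each_epoch:
                    # fresh vertical-axis rotation per cloud per epoch; mirrors
                    # the dataset pipeline's rotation augmentation
                    theta = rng.uniform(0, 2 * np.pi)
                    c, s = np.cos(theta), np.sin(theta)
                    rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]],
                                   dtype=xb.dtype)
                    xb[j] = xb[j] @ rot.T
            probs = model.forward(xb)
            loss = loss_fn(probs, yb)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(loss.item())
        record = {"epoch": epoch, "lr": lr,
                  "train_loss": float(np.mean(epoch_losses))}
        last = epoch == train_config.epochs - 1
        if x_val is not None and (epoch % train_config.eval_every == 0 or last):
            rep, _, val_loss = evaluate(model, x_val, y_val, loss_fn,
                                        train_config.batch_size)
            record.update(val_loss=val_loss, val_miou=rep.miou,
                          val_mf1=rep.mf1)
        history.append(**record)
        if log is not None:
            log(" ".join(f"{k}={v:.5g}" if isinstance(v, float) else f"{k}={v}"
                         for k, v in record.items()))
    return history


def save_checkpoint(path: str, model: StemSegNet, train_config: TrainConfig,
                    loss_config: LossConfig, history: TrainHistory | None = None
                    ) -> None:
    meta = {"model": asdict(model.config), "train": asdict(train_config),
            "loss": asdict(loss_config),
            "history": history.epochs if history else []}
    arrays = {k.replace(":", "__"): v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str) -> tuple[StemSegNet, TrainConfig, LossConfig, list]:
    data = np.load(path if path.endswith(".npz") else path + ".npz")
    meta = json.loads(bytes(data["__meta__"]).decode())
    model = StemSegNet(ModelConfig(**meta["model"]))
    state = {k.replace("__", ":", 1): data[k] for k in data.files
             if k != "__meta__"}
    model.load_state_dict(state)
    return (model, TrainConfig(**meta["train"]), LossConfig(**meta["loss"]),
            meta["history"])


def segment_cloud(model: StemSegNet, cloud: LabeledCloud, seed: int = 0
                  ) -> LabeledCloud:
    """Predict per-point stem/other labels for a cloud of any size.

    The cloud is normalized and resampled to the model's point count for
    inference; predictions are mapped back to the original resolution through
    nearest-neighbor lookup, so the output has exactly the input's points.
    """
    from scipy.spatial import cKDTree

    normed, _ = normalize(cloud)
    fixed = resample_fixed(normed, model.config.n_points, seed=seed)
    pred = model.predict(fixed.points.astype(np.float32))
    tree = cKDTree(fixed.points)
    _, nearest = tree.query(normed.points)
    return LabeledCloud(cloud.points, pred[nearest], cloud.origin_id,
                        cloud.variant)


def cross_validate(model_config: ModelConfig, train_config: TrainConfig,
                   loss_config: LossConfig, manifest: DatasetManifest,
                   k: int | None = None, log=None
                   ) -> tuple[list[TrainHistory], list[MetricReport], MetricReport]:
    """Grouped k-fold CV: every origin validates exactly once.

    Returns (per-fold histories, per-fold reports, pooled report from the
    summed confusion counts of all folds).
    """
    k = k or train_config.folds
    folds = kfold_grouped(manifest, k, seed=train_config.seed)
    histories, fold_reports = [], []
    pooled = EvalCounts.zeros(model_config.num_classes)
    paths = manifest.entries["path"].to_numpy()
    clouds = [read_cloud(p) for p in paths]
    x_all, y_all = prepare_clouds(clouds, model_config.n_points,
                                  seed=train_config.seed)
    for f, split in enumerate(folds):
        model = StemSegNet(model_config)
        hist = train(model, x_all[split.train], y_all[split.train],
                     train_config, loss_config,
                     x_all[split.test], y_all[split.test], log=log)
        rep, counts, _ = evaluate(model, x_all[split.test], y_all[split.test])
        histories.append(hist)
        fold_reports.append(rep)
        pooled = pooled + counts
        if log is not None:
            log(f"fold {f}: val mIoU {rep.miou:.1f}%")
    return histories, fold_reports, report(pooled)
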