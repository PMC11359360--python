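"""Desk-scale end-to-end benchmark on synthetic scenes.

Generates a dataset of synthetic seedling scenes spanning all scene families,
splits it 4:1 grouped by origin, trains the full attention model with the
hybrid cross-entropy + Dice loss, trains the attention-free cross-entropy
baseline under the identical schedule, and evaluates both on the held-out
origins. The default problem size — 120 scenes of 1024 points, 0.75-width
channels (48, 96, 192, 384, 768), 30 epochs — is the package's reference
desk-scale configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .backbone import StemSegNet
from .config import LossConfig, ModelConfig, TrainConfig, REDUCED_CHANNELS
from .datasets import DatasetManifest, split_grouped
from .metrics import MetricReport
from .scenes import default_spec_sampler, generate_scene
from .training import TrainHistory, evaluate, prepare_clouds, train

__all__ = ["BenchmarkResult", "benchmark_config", "make_benchmark_data",
           "run_benchmark"]


@dataclass
class BenchmarkResult:
    full: MetricReport
    baseline: MetricReport
    full_history: TrainHistory
    baseline_history: TrainHistory
    n_train: int
    n_test: int


def benchmark_config(seed: int = 0, n_points: int = 1024
                     ) -> tuple[ModelConfig, TrainConfig, LossConfig]:
    model = ModelConfig(n_points=n_points, channels=list(REDUCED_CHANNELS),
                        group_size=32, head_dropout=0.0, seed=seed)
    trainer = TrainConfig(batch_size=6, epochs=30, seed=seed, eval_every=5)
    loss = LossConfig(name="hce")
    return model, trainer, loss


def make_benchmark_data(n_scenes: int = 120, n_points: int = 1024,
                        seed: int = 0
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Scenes from the default sampler, split 4:1 grouped, as training arrays."""
    rng = np.random.default_rng(seed)
    clouds = []
    rows = []
    for i in range(n_scenes):
        spec = replace(default_spec_sampler(rng), points_total=n_points)
        bundle = generate_scene(spec)
        bundle.cloud.origin_id = f"scene_{i:04d}"
        clouds.append(bundle.cloud)
        rows.append({"path": f"scene_{i:04d}", "origin_id": f"scene_{i:04d}",
                     "variant": "original", "split": "none"})
    manifest = DatasetManifest(rows)
    result = split_grouped(manifest, "4:1", seed)
    x, y = prepare_clouds(clouds, n_points, seed)
    return x[result.train], y[result.train], x[result.test], y[result.test]


def run_benchmark(seed: int = 0, n_scenes: int = 120, n_points: int = 1024,
                  epochs: int = 30, log=None,
                  track_validation: bool = False) -> BenchmarkResult:
    """Train full model and attention-free baseline on identical data/schedule.

    ``track_validation`` adds held-out metrics to the training history every
    few epochs (useful for curves, not needed for the final report).
    """
    model_cfg, train_cfg, loss_cfg = benchmark_config(seed, n_points)
    train_cfg.epochs = epochs
    x_tr, y_tr, x_te, y_te = make_benchmark_data(n_scenes, n_points, seed)
    val = (x_te, y_te) if track_validation else (None, None)

    full = StemSegNet(model_cfg)
    full_hist = train(full, x_tr, y_tr, train_cfg, loss_cfg, *val, log=log)
    full_rep, _, _ = evaluate(full, x_te, y_te)

    base_cfg = replace(model_cfg, cra_enabled=False, pesa_enabled=False)
    baseline = StemSegNet(base_cfg)
    base_hist = train(baseline, x_tr, y_tr, train_cfg, LossConfig(name="ce"),
                      *val, log=log)
    base_rep, _, _ = evaluate(baseline, x_te, y_te)

    return BenchmarkResult(full=full_rep, baseline=base_rep,
                           full_history=full_hist, baseline_history=base_hist,
                           n_train=len(x_tr), n_test=len(x_te))
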