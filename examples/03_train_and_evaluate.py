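"""Train a small model on synthetic scenes and evaluate it.

Uses a deliberately tiny problem (40 scenes of 512 points, 10 epochs,
narrow widths) so the script finishes in about a minute on one CPU; the
reference desk-scale configuration lives in stemseg.benchmark.
"""

from dataclasses import replace

import numpy as np

from stemseg.backbone import StemSegNet
from stemseg.config import LossConfig, ModelConfig, TrainConfig
from stemseg.datasets import DatasetManifest, split_grouped
from stemseg.scenes import default_spec_sampler, generate_scene
from stemseg.training import evaluate, prepare_clouds, train

rng = np.random.default_rng(0)
clouds = []
rows = []
for i in range(40):
    spec = replace(default_spec_sampler(rng), points_total=512)
    bundle = generate_scene(spec)
    bundle.cloud.origin_id = f"scene_{i:03d}"
    clouds.append(bundle.cloud)
    rows.append({"path": str(i), "origin_id": bundle.cloud.origin_id,
                 "variant": "original", "split": "none"})

split = split_grouped(DatasetManifest(rows), "4:1", seed=0)
x, y = prepare_clouds(clouds, 512, seed=0)

model = StemSegNet(ModelConfig(n_points=512, channels=[16, 32, 64, 128, 256],
                               group_size=12, seed=0))
history = train(model, x[split.train], y[split.train],
                TrainConfig(epochs=10, batch_size=6, seed=0, eval_every=5),
                LossConfig(name="hce"),
                x[split.test], y[split.test], log=print)

report, _, _ = evaluate(model, x[split.test], y[split.test])
print()
print(f"held-out ({len(split.test)} scenes): mIoU {report.miou:.1f}%  "
      f"mP {report.mp:.1f}%  mR {report.mr:.1f}%  mF1 {report.mf1:.1f}%")
print("mIoU averages the stem and non-stem intersection-over-union; the")
print("stem class dominates the error because it is the small class.")
print("per-class:", {k: round(v["iou"], 1) for k, v in report.per_class.items()})
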