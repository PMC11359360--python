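"""Configuration dataclasses for the model, loss and training loop."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

__all__ = ["ModelConfig", "LossConfig", "TrainConfig", "RunConfig"]

FULL_CHANNELS = [64, 128, 256, 512, 1024]
REDUCED_CHANNELS = [48, 96, 192, 384, 768]  # 0.75-width desk-scale schedule


@dataclass
class ModelConfig:
    """Architecture schedule.

    The encoder retains 25% of the points per stage (N -> N/4 -> ... -> N/256)
    while widening features along ``channels``; the decoder mirrors the
    encoder widths in reverse. ``channels[0]`` is the width of the initial
    per-point lift, ``channels[1:]`` the four set-abstraction outputs.
    """

    n_points: int = 4096
    channels: list = field(default_factory=lambda: list(FULL_CHANNELS))
    group_size: int = 32
    radii: list = field(default_factory=lambda: [0.1, 0.2, 0.4, 0.8])
    se_reduction: int = 4
    cra_enabled: bool = True
    pesa_enabled: bool = True
    pesa_placement: str = "bottleneck"  # "bottleneck" (default) or "all" stages
    position_gate: str = "gram"  # "gram" (default Eq-style gate) or "none"
    head_dropout: float = 0.0  # optional dropout before the classifier
    num_classes: int = 2
    seed: int = 0

    @property
    def stages(self) -> int:
        return len(self.radii)

    @property
    def decoder_channels(self) -> list:
        return list(reversed(self.channels[:-1]))

    def validate(self):
        if len(self.channels) != self.stages + 1:
            raise ValueError("channels must have one more entry than radii")
        if self.n_points % 4**self.stages:
            raise ValueError(
                f"n_points={self.n_points} must be divisible by 4^{self.stages}")
        for c in self.channels:
            if c % self.se_reduction:
                raise ValueError(f"channel width {c} not divisible by "
                                 f"se_reduction={self.se_reduction}")
        if self.pesa_placement not in ("all", "bottleneck"):
            raise ValueError("pesa_placement must be 'all' or 'bottleneck'")
        return self

    @property
    def point_schedule(self) -> list:
        return [self.n_points // 4**s for s in range(self.stages + 1)]


@dataclass
class LossConfig:
    """Hybrid loss weights; both zero is a configuration error."""

    name: str = "hce"  # ce | dice | hce
    weight_ce: float = 0.5
    weight_dice: float = 0.5
    epsilon: float = 1e-5

    def validate(self):
        if self.weight_ce < 0 or self.weight_dice < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.name == "hce" and self.weight_ce + self.weight_dice == 0:
            raise ValueError("at least one loss weight must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        return self


@dataclass
class TrainConfig:
    """Optimizer schedule: Adam (first-moment 0.9), cosine lr decay."""

    batch_size: int = 6
    lr_init: float = 1e-3
    lr_min: float = 1e-5
    epochs: int = 150
    momentum: float = 0.9
    seed: int = 0
    folds: int = 5
    eval_every: int = 1
    rotate_each_epoch: bool = False  # optional train-time vertical-axis rotation

    def validate(self):
        if self.lr_min > self.lr_init:
            raise ValueError("lr_min must not exceed lr_init")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        return self


@dataclass
class RunConfig:
    """Nested configuration for the end-to-end pipeline."""

    model: ModelConfig = field(default_factory=ModelConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    n_origins: int = 20
    scene_points: int = 4096
    split_ratio: str = "4:1"
    filter_k: int = 16
    filter_std_ratio: float = 2.0
    out_dir: str = "runs"
    seed: int = 0

    def validate(self):
        self.model.validate()
        self.loss.validate()
        self.train.validate()
        return self

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for section, klass in (("model", ModelConfig), ("loss", LossConfig),
                               ("train", TrainConfig)):
            if section in raw:
                setattr(cfg, section, klass(**raw.pop(section)))
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            setattr(cfg, key, value)
        return cfg.validate()

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
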