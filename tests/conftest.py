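import numpy as np
import pytest

from stemseg.config import ModelConfig
from stemseg.io import LabeledCloud


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_cloud(rng):
    """Small labeled cloud: 60 points on a vertical stick + 140 scattered."""
    stick = np.column_stack([
        rng.normal(0, 0.01, 60), rng.normal(0, 0.01, 60), rng.uniform(0, 1, 60)])
    blob = rng.uniform(-0.5, 0.5, (140, 3))
    pts = np.vstack([stick, blob])
    labels = np.concatenate([np.ones(60, dtype=int), np.zeros(140, dtype=int)])
    return LabeledCloud(pts, labels, origin_id="fixture")


@pytest.fixture
def tiny_model_config():
    """Smallest config the architecture supports: 256 points, narrow widths."""
    return ModelConfig(n_points=256, channels=[8, 16, 32, 64, 128],
                       group_size=8, radii=[0.2, 0.4, 0.8, 1.6], seed=7)
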