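"""Statistical outlier removal and the three-way augmentation.

Generates a noisy scene, removes outliers with the k-nearest-neighbor
statistical filter, then shows the three augmentations used to expand a
dataset fourfold.
"""

import numpy as np

from stemseg.preprocess import AugmentParams, FilterParams, augment_jitter, \
    augment_noise, augment_rotation, statistical_outlier_removal
from stemseg.scenes import SceneSpec, generate_scene

bundle = generate_scene(SceneSpec(points_total=2048, outlier_rate=0.08, seed=3))
cloud = bundle.cloud
print(f"scene: {len(cloud)} points, {len(bundle.truth_masks['outlier'])} "
      "of them uniform outliers")

kept, removed = statistical_outlier_removal(
    cloud, FilterParams(k_neighbors=16, std_ratio=2.0))
hit = np.isin(removed, bundle.truth_masks["outlier"]).mean()
print(f"filter removed {len(removed)} points; {hit:.0%} of removals were "
      "true outliers")

rng = np.random.default_rng(0)
params = AugmentParams(jitter_sigma=0.01, jitter_clip=0.05, noise_sigma=0.02)
rotated = augment_rotation(kept, rng)
jittered = augment_jitter(kept, params, rng)
noised = augment_noise(kept, params, rng)
for variant in (rotated, jittered, noised):
    shift = np.abs(variant.points - kept.points).max()
    print(f"variant {variant.variant!r}: max per-coordinate shift {shift:.3f}")
print("rotation is an isometry (large coordinate shifts, distances kept);")
print("jitter is clipped at 0.05; Gaussian noise is unclipped.")
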