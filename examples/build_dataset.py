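"""Generate a scene dataset with the 8:2 split and augmentation doubling.

Mirrors the dataset bookkeeping of a field collection: draw scenes across
the four weather regimes, split 8:2 into train/validation, and double the
set by giving every scene one augmented variant (translation, rotation,
contrast or brightness).
"""

from collections import Counter

from saffpick.synth import (
    WEATHER_REGIMES, SceneSpec, expand_dataset, generate_dataset,
)

base = SceneSpec(noise_sigma=3.0).scaled(0.25)  # 120x160 scenes
samples, split = generate_dataset(
    40,
    spec_ranges={"weather": list(WEATHER_REGIMES),
                 "branch_angle_deg": (-10.0, 10.0)},
    seed=0,
    base_spec=base,
)
print(f"generated {len(samples)} scenes "
      f"({Counter(s.spec.weather for s in samples)})")
print(f"split: {len(split['train'])} train / {len(split['val'])} validation")

doubled = expand_dataset(samples, seed=1)
print(f"after augmentation doubling: {len(doubled)} scenes")
s = doubled[len(samples)]  # first augmented variant
print(f"augmented ground-truth necking moved to "
      f"({s.gt_necking.x:.1f}, {s.gt_necking.y:.1f})")
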