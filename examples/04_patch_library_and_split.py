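"""Build the labelled patch library and the train/val/test split.

Each scene is quadrant-tiled and canopy patches (15x15 pixels through all
223 bands) are sampled per quadrant.  The split is stratified 3:1
train-test, then 80:20 train-validation.  Printed numbers: library size,
per-class balance and the split arithmetic.
"""

from hsin.patches import SplitSpec, split_dataset
from hsin.pipeline import PipelineConfig, build_patch_library
from hsin.synth import SceneSpec, generate_dataset

cfg = PipelineConfig(
    n_scenes_per_treatment=3,
    scene=SceneSpec(height=64, width=64),
    patches_per_quadrant=5,
    seed=0,
)
scenes = generate_dataset(3, cfg.scene, seed=0)
library = build_patch_library(scenes, cfg)
print(f"{len(scenes)} scenes -> {len(library)} patches "
      f"({cfg.patches_per_quadrant} per quadrant x 4 quadrants per scene)")
print("per-class counts:", library.class_counts())

train, val, test = split_dataset(library, SplitSpec(seed=0))
print(f"split train/val/test = {len(train)}/{len(val)}/{len(test)} "
      "(3:1 train-test, then 80:20 train-validation)")
print("patch tensor shape:", library.data.shape[1:], "(rows, cols, bands)")
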