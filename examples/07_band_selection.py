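"""Select informative wavebands with greedy correlation-based selection.

CFS scores a band subset by high class correlation and low mutual
correlation; greedy forward search adds the merit-maximising band until no
candidate improves it.  Printed numbers: the selected wavelengths and the
merit trace.  On the synthetic treatments the picks cluster where the class
profiles actually differ (green peak, red edge, NIR plateau, SWIR water
dip) rather than in featureless parts of the grid.
"""

from hsin.patches import SplitSpec, split_dataset
from hsin.pipeline import (
    PipelineConfig,
    apply_transform,
    build_patch_library,
    select_bands,
)
from hsin.synth import SceneSpec, generate_dataset

cfg = PipelineConfig(
    n_scenes_per_treatment=3,
    scene=SceneSpec(height=64, width=64),
    patches_per_quadrant=3,
    seed=0,
    split=SplitSpec(seed=0),
)
scenes = generate_dataset(3, cfg.scene, seed=0)
library = build_patch_library(scenes, cfg)
tr, va, te = split_dataset(library, cfg.split)
trT, _, _, _ = apply_transform(tr, va, te, "sderi", cfg)

sel = select_bands(trT, max_bands=10)
print(f"selected {len(sel)} of {trT.data.shape[-1]} bands:")
for wl, idx, merit in zip(sel.selected_wavelengths, sel.selected_indices,
                          sel.merit_trace):
    print(f"  band {idx:3d}  {wl:7.1f} nm   merit {merit:.3f}")
print("merit is non-decreasing; search stops when no band improves it")
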