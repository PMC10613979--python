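"""Segment plant from background with the red-edge NDVI + Otsu threshold.

The index (R750 - R705)/(R750 + R705) is high on canopy (steep red edge)
and ~0 on the flat background; Otsu finds the separating threshold
automatically.  Printed numbers: the threshold and the intersection-over-
union against the generator's ground-truth mask (1.0 = perfect recovery).
"""

import numpy as np

from hsin.hsi_io import calibrate
from hsin.segmentation import normalized_difference, segment_plant
from hsin.synth import SceneSpec, default_profiles, generate_scene

scene = generate_scene(
    SceneSpec(), default_profiles()["LNHP"], rng=np.random.default_rng(1)
)
cal = calibrate(scene.vnir.raw, scene.vnir.refs)

index = normalized_difference(cal, 750.0, 705.0)
mask = segment_plant(cal)

print(f"RENDVI on canopy    : {index[scene.mask].mean():.3f}")
print(f"RENDVI on background: {index[~scene.mask].mean():.3f}")
print(f"Otsu threshold      : {mask.threshold:.3f}")
print(f"IoU vs ground truth : {mask.iou(scene.mask):.4f} (>0.95 under default noise)")
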