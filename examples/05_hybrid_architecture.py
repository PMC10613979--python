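"""Inspect the hybrid 3D-2D CNN architecture and its parameter budget.

Prints the layer table (output shape + parameter count per layer) for the
default 15x15x223 patch input.  The model stays under 200k trainable
parameters -- the point of folding the 3-D block into a separable 2-D
convolution instead of stacking more 3-D layers.
"""

from hsin.models import build_hybrid_cnn, count_parameters

spec = build_hybrid_cnn(input_shape=(15, 15, 223, 1), n_classes=4)
rows, total, trainable = count_parameters(spec)

print(f"{'layer':<22}{'output shape':<20}{'params':>8}")
for name, shape, n, _ in rows:
    print(f"{name:<22}{str(shape):<20}{n:>8}")
print("-" * 50)
print(f"total parameters      {total:>8}")
print(f"trainable parameters  {trainable:>8}  (< 200,000)")
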