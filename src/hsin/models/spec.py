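"""Declarative CNN architecture descriptions with exact parameter counting.

A :class:`ModelSpec` is an ordered list of :class:`LayerSpec` entries plus an
input shape.  Shape inference propagates valid-padding arithmetic layer by
layer, and :func:`count_parameters` reproduces the framework-style parameter
table (convNd: ``(prod(kernel) * in_ch + 1) * filters``; separable conv2d:
``kh*kw*in_ch + (in_ch + 1) * filters``; dense: ``(in + 1) * units``; batch
normalisation: ``4 * channels`` of which half are trainable).

Four architectures are provided: the proposed hybrid 3D-2D network (three 3-D
convolutions feeding a depthwise-separable 2-D block), HybridSN, a
homogeneous 3D-CNN and a LeNet-style 2D-CNN that consumes the bands as input
channels.  When the spectral axis is shorter than a 3-D kernel or pool (e.g.
for a 3-channel LDA representation) the spectral extent is clipped to the
available depth; the default 223-band input never triggers clipping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from math import prod
from typing import Optional

from ..exceptions import InvalidParameterError, ShapeInferenceError

__all__ = [
    "LayerSpec",
    "ModelSpec",
    "TrainConfig",
    "infer_shapes",
    "count_parameters",
    "build_hybrid_cnn",
    "build_hybridsn",
    "build_3dcnn",
    "build_2dcnn",
    "ARCHITECTURES",
]


@dataclass
class LayerSpec:
    kind: str  # conv3d | batchnorm | maxpool3d | reshape3d2d | sepconv2d |
    # conv2d | maxpool2d | avgpool2d | flatten | dense | dropout | softmax
    name: str = ""
    kernel: Optional[tuple] = None
    filters: Optional[int] = None
    units: Optional[int] = None
    stride: Optional[tuple] = None
    padding: str = "valid"
    activation: Optional[str] = None  # relu | softmax | None
    rate: Optional[float] = None
    pool: Optional[tuple] = None

    def __post_init__(self):
        if self.kernel is not None and any(k <= 0 for k in self.kernel):
            raise InvalidParameterError(f"kernel dims must be positive: {self.kernel}")
        if self.rate is not None and not 0.0 <= self.rate < 1.0:
            raise InvalidParameterError(f"dropout rate {self.rate} outside [0, 1)")


@dataclass
class ModelSpec:
    name: str
    input_shape: tuple  # (m, n, k, channels) for 3-D nets, (m, n, channels) for 2-D
    layers: list
    n_classes: int

    def to_json(self) -> dict:
        return {
            "name": self.name,
            "input_shape": list(self.input_shape),
            "n_classes": self.n_classes,
            "layers": [asdict(l) for l in self.layers],
        }


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults: Adam 1e-3, batch 32, 100 epochs)."""

    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 100
    early_stopping_patience: int = 10
    loss: str = "categorical_crossentropy"
    seed: int = 0
    standardize_inputs: bool = True
    shuffle: bool = True

    def __post_init__(self):
        for name in ("learning_rate", "batch_size"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.epochs < 0:
            raise InvalidParameterError("epochs must be >= 0")


def _check_positive(shape, layer: LayerSpec, index: int):
    if any(int(d) <= 0 for d in shape):
        raise ShapeInferenceError(
            f"layer {index} ({layer.name or layer.kind}): inferred shape "
            f"{tuple(shape)} has a non-positive dimension; input too small "
            "for the receptive chain"
        )


def infer_shapes(spec: ModelSpec) -> list:
    """Output shape (excluding the batch axis) after every layer."""
    shape = tuple(spec.input_shape)
    out = []
    for i, layer in enumerate(spec.layers):
        k = layer.kind
        if k == "conv3d":
            h, w, d, c = shape
            kh, kw, kd = layer.kernel
            shape = (h - kh + 1, w - kw + 1, d - kd + 1, layer.filters)
        elif k == "sepconv2d" or k == "conv2d":
            h, w, c = shape
            kh, kw = layer.kernel
            shape = (h - kh + 1, w - kw + 1, layer.filters)
        elif k == "maxpool3d":
            h, w, d, c = shape
            p = layer.pool
            shape = (h // p[0], w // p[1], d // p[2], c)
        elif k in ("maxpool2d", "avgpool2d"):
            h, w, c = shape
            p = layer.pool
            shape = (h // p[0], w // p[1], c)
        elif k == "batchnorm" or k == "dropout" or k == "softmax":
            pass
        elif k == "reshape3d2d":
            h, w, d, c = shape
            shape = (h, w, d * c)
        elif k == "flatten":
            shape = (prod(shape),)
        elif k == "dense":
            shape = (layer.units,)
        else:
            raise InvalidParameterError(f"unknown layer kind {k!r}")
        _check_positive(shape, layer, i)
        out.append(shape)
    return out


def count_parameters(spec: ModelSpec):
    """Per-layer parameter table and totals.

    Returns ``(rows, total, total_trainable)`` where each row is
    ``(name, output_shape, n_params, n_trainable)``.  Batch normalisation
    contributes ``4 * channels`` parameters of which ``2 * channels`` are
    trainable (the other half are running statistics).
    """
    shapes = infer_shapes(spec)
    in_shape = tuple(spec.input_shape)
    rows = []
    for layer, out_shape in zip(spec.layers, shapes):
        k = layer.kind
        if k == "conv3d":
            c = in_shape[-1]
            n = (prod(layer.kernel) * c + 1) * layer.filters
            t = n
        elif k == "conv2d":
            c = in_shape[-1]
            n = (prod(layer.kernel) * c + 1) * layer.filters
            t = n
        elif k == "sepconv2d":
            c = in_shape[-1]
            n = prod(layer.kernel) * c + (c + 1) * layer.filters
            t = n
        elif k == "batchnorm":
            c = in_shape[-1]
            n = 4 * c
            t = 2 * c
        elif k == "dense":
            n = (prod(in_shape) + 1) * layer.units
            t = n
        else:
            n = t = 0
        rows.append((layer.name or k, out_shape, n, t))
        in_shape = out_shape
    total = sum(r[2] for r in rows)
    trainable = sum(r[3] for r in rows)
    return rows, total, trainable


def _clip_spectral(extent: int, depth: int) -> int:
    return max(1, min(extent, depth))


def build_hybrid_cnn(
    input_shape: tuple = (15, 15, 223, 1), n_classes: int = 4
) -> ModelSpec:
    """The proposed hybrid 3D-2D CNN.

    Three valid-padded ReLU 3-D convolutions (8, 8, 16 filters, all 3x3x3
    kernels, batch normalisation after the first two), 2x2x2 max pooling, a
    reshape folding (bands x filters) into 2-D channels in band-major order,
    one depthwise-separable 3x3 convolution with 32 filters, 2x2 max pooling,
    then dense 256 -> 128 heads with 0.5 dropout and a softmax output.
    """
    d = input_shape[2]
    layers = []

    def conv3(filters, name, bn):
        nonlocal d
        kd = _clip_spectral(3, d)
        layers.append(
            LayerSpec("conv3d", name, kernel=(3, 3, kd), filters=filters,
                      activation="relu")
        )
        d = d - kd + 1
        if bn:
            layers.append(LayerSpec("batchnorm", f"{name}_bn"))

    conv3(8, "conv3d", bn=True)
    conv3(8, "conv3d_1", bn=True)
    conv3(16, "conv3d_2", bn=False)
    pd = _clip_spectral(2, d)
    layers += [
        LayerSpec("maxpool3d", "maxpool3d", pool=(2, 2, pd)),
        LayerSpec("reshape3d2d", "reshape_3d_2d"),
        LayerSpec("sepconv2d", "separable_conv2d", kernel=(3, 3), filters=32,
                  activation="relu"),
        LayerSpec("maxpool2d", "maxpool2d", pool=(2, 2)),
        LayerSpec("flatten", "flatten"),
        LayerSpec("dense", "dense", units=256, activation="relu"),
        LayerSpec("dropout", "dropout", rate=0.5),
        LayerSpec("dense", "dense_1", units=128, activation="relu"),
        LayerSpec("dropout", "dropout_1", rate=0.5),
        LayerSpec("dense", "dense_2", units=n_classes, activation="softmax"),
    ]
    spec = ModelSpec("hybrid", tuple(input_shape), layers, n_classes)
    infer_shapes(spec)  # fail fast on too-small inputs
    return spec


def build_hybridsn(
    input_shape: tuple = (15, 15, 223, 1), n_classes: int = 4
) -> ModelSpec:
    """HybridSN comparator: 3-D convolutions (8, 16, 32 filters; kernels
    3x3x3, 3x3x5, 3x3x3) feeding a classical 3x3 2-D convolution with 64
    filters, then dense 256 -> 128 with dropout and softmax."""
    d = input_shape[2]
    layers = []
    for filters, kd_want, name in ((8, 3, "conv3d"), (16, 5, "conv3d_1"),
                                   (32, 3, "conv3d_2")):
        kd = _clip_spectral(kd_want, d)
        layers.append(
            LayerSpec("conv3d", name, kernel=(3, 3, kd), filters=filters,
                      activation="relu")
        )
        d = d - kd + 1
    layers += [
        LayerSpec("reshape3d2d", "reshape_3d_2d"),
        LayerSpec("conv2d", "conv2d", kernel=(3, 3), filters=64, activation="relu"),
        LayerSpec("flatten", "flatten"),
        LayerSpec("dense", "dense", units=256, activation="relu"),
        LayerSpec("dropout", "dropout", rate=0.4),
        LayerSpec("dense", "dense_1", units=128, activation="relu"),
        LayerSpec("dropout", "dropout_1", rate=0.4),
        LayerSpec("dense", "dense_2", units=n_classes, activation="softmax"),
    ]
    spec = ModelSpec("hybridsn", tuple(input_shape), layers, n_classes)
    infer_shapes(spec)
    return spec


def build_3dcnn(
    input_shape: tuple = (15, 15, 223, 1), n_classes: int = 4
) -> ModelSpec:
    """Homogeneous 3D-CNN comparator.

    Four ReLU 3-D convolutions (first kernel 3x3x3, the rest 3x3x5; filters
    8/16/32/64) with max pooling + batch normalisation after every pair of
    convolutions, dropout 0.5 after the first pooling, and dense 256 -> 128
    heads with softmax.  The second pool acts on the spectral axis only
    because the spatial extent is exhausted by then.
    """
    d = input_shape[2]
    layers = []

    def conv3(filters, kd_want, name):
        nonlocal d
        kd = _clip_spectral(kd_want, d)
        layers.append(
            LayerSpec("conv3d", name, kernel=(3, 3, kd), filters=filters,
                      activation="relu")
        )
        d = d - kd + 1

    conv3(8, 3, "conv3d")
    conv3(16, 5, "conv3d_1")
    pd = _clip_spectral(2, d)
    layers += [
        LayerSpec("maxpool3d", "maxpool3d", pool=(2, 2, pd)),
        LayerSpec("batchnorm", "bn"),
        LayerSpec("dropout", "dropout", rate=0.5),
    ]
    d //= pd
    conv3(32, 5, "conv3d_2")
    conv3(64, 5, "conv3d_3")
    pd = _clip_spectral(2, d)
    layers += [
        LayerSpec("maxpool3d", "maxpool3d_1", pool=(1, 1, pd)),
        LayerSpec("batchnorm", "bn_1"),
        LayerSpec("flatten", "flatten"),
        LayerSpec("dense", "dense", units=256, activation="relu"),
        LayerSpec("dense", "dense_1", units=128, activation="relu"),
        LayerSpec("dense", "dense_2", units=n_classes, activation="softmax"),
    ]
    spec = ModelSpec("cnn3d", tuple(input_shape), layers, n_classes)
    infer_shapes(spec)
    return spec


def build_2dcnn(input_shape: tuple = (15, 15, 223), n_classes: int = 4) -> ModelSpec:
    """LeNet-style 2-D comparator consuming the bands as input channels.

    Two 3x3 stride-1 valid convolutions (6 then 12 filters) each followed by
    2x2 stride-2 average pooling, then dense layers of 120 and 140 units and
    a softmax output.
    """
    layers = [
        LayerSpec("conv2d", "conv2d", kernel=(3, 3), filters=6, stride=(1, 1),
                  activation="relu"),
        LayerSpec("avgpool2d", "avgpool2d", pool=(2, 2)),
        LayerSpec("conv2d", "conv2d_1", kernel=(3, 3), filters=12, stride=(1, 1),
                  activation="relu"),
        LayerSpec("avgpool2d", "avgpool2d_1", pool=(2, 2)),
        LayerSpec("flatten", "flatten"),
        LayerSpec("dense", "dense", units=120, activation="relu"),
        LayerSpec("dense", "dense_1", units=140, activation="relu"),
        LayerSpec("dense", "dense_2", units=n_classes, activation="softmax"),
    ]
    spec = ModelSpec("cnn2d", tuple(input_shape), layers, n_classes)
    infer_shapes(spec)
    return spec


ARCHITECTURES = {
    "hybrid": build_hybrid_cnn,
    "hybridsn": build_hybridsn,
    "cnn3d": build_3dcnn,
    "cnn2d": build_2dcnn,
}
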