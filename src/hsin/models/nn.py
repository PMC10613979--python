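"""NumPy runtime for the declarative architectures: forward, backprop, Adam.

Convolutions are valid-padded, stride 1, and evaluated by kernel-offset
accumulation (one small matrix product per kernel offset), which keeps peak
memory low and routes the arithmetic through BLAS.  Training is plain
mini-batch SGD with Adam, categorical cross-entropy, optional early stopping
on validation accuracy, and is deterministic given the seed (single-threaded
NumPy has no nondeterministic reductions at these sizes).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from ..exceptions import InvalidInputError
from .spec import ModelSpec, TrainConfig

__all__ = ["compile_network", "train", "predict", "TrainedModel"]

_F = np.float32


class _Layer:
    """Base layer: parameter-free, shape-preserving by default."""

    params: list
    grads: list

    def __init__(self):
        self.params, self.grads = [], []
        self.needs_input_grad = True  # cleared on the first layer of a network

    def forward(self, x, training):
        return x

    def backward(self, d):
        return d


def _relu_forward(layer, z):
    np.maximum(z, 0, out=z)
    layer._relu_out = z  # mask recoverable as z > 0
    return z


def _relu_backward(layer, d):
    d = d * (layer._relu_out > 0)
    layer._relu_out = None
    return d


class Conv3D(_Layer):
    def __init__(self, kernel, in_ch, filters, activation, rng):
        super().__init__()
        kh, kw, kd = kernel
        fan_in = kh * kw * kd * in_ch
        self.W = rng.normal(0, np.sqrt(2.0 / fan_in),
                            (kh, kw, kd, in_ch, filters)).astype(_F)
        self.b = np.zeros(filters, dtype=_F)
        self.kernel, self.activation = kernel, activation
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training):
        from numpy.lib.stride_tricks import sliding_window_view

        kh, kw, kd = self.kernel
        B, H, Wd, D, C = x.shape
        Ho, Wo, Do = H - kh + 1, Wd - kw + 1, D - kd + 1
        F = self.b.size
        out = np.empty((B, Ho, Wo, Do, F), dtype=_F)
        out[:] = self.b
        tmp = np.empty_like(out)
        if C == 1:
            # single-channel input: contract the spectral window in one GEMM
            xs_spec = sliding_window_view(x[..., 0], kd, axis=3)  # (B,H,W,Do,kd)
            for i, j in product(range(kh), range(kw)):
                np.matmul(
                    xs_spec[:, i : i + Ho, j : j + Wo], self.W[i, j, :, 0, :],
                    out=tmp,
                )
                out += tmp
        else:
            for i, j, l in product(range(kh), range(kw), range(kd)):
                xs = x[:, i : i + Ho, j : j + Wo, l : l + Do, :]
                np.matmul(xs, self.W[i, j, l], out=tmp)
                out += tmp
        self._x = x
        return _relu_forward(self, out) if self.activation == "relu" else out

    def backward(self, d):
        if self.activation == "relu":
            d = _relu_backward(self, d)
        x = self._x
        kh, kw, kd = self.kernel
        B, Ho, Wo, Do, F = d.shape
        C = x.shape[-1]
        dW, db = self.grads
        db[:] = d.sum(axis=(0, 1, 2, 3))
        d2 = np.ascontiguousarray(d).reshape(-1, F)
        dx = np.zeros_like(x) if self.needs_input_grad else None
        buf = np.empty((d2.shape[0], C), dtype=_F) if self.needs_input_grad else None
        for i, j, l in product(range(kh), range(kw), range(kd)):
            xs = np.ascontiguousarray(
                x[:, i : i + Ho, j : j + Wo, l : l + Do, :]
            ).reshape(-1, C)
            dW[i, j, l] = xs.T @ d2
            if dx is not None:
                np.matmul(d2, self.W[i, j, l].T, out=buf)
                dx[:, i : i + Ho, j : j + Wo, l : l + Do, :] += buf.reshape(
                    B, Ho, Wo, Do, C
                )
        self._x = None
        return dx


class Conv2D(_Layer):
    def __init__(self, kernel, in_ch, filters, activation, rng):
        super().__init__()
        kh, kw = kernel
        fan_in = kh * kw * in_ch
        self.W = rng.normal(0, np.sqrt(2.0 / fan_in),
                            (kh, kw, in_ch, filters)).astype(_F)
        self.b = np.zeros(filters, dtype=_F)
        self.kernel, self.activation = kernel, activation
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training):
        kh, kw = self.kernel
        B, H, Wd, C = x.shape
        Ho, Wo = H - kh + 1, Wd - kw + 1
        out = np.empty((B, Ho, Wo, self.b.size), dtype=_F)
        out[:] = self.b
        for i, j in product(range(kh), range(kw)):
            out += x[:, i : i + Ho, j : j + Wo, :] @ self.W[i, j]
        self._x = x
        return _relu_forward(self, out) if self.activation == "relu" else out

    def backward(self, d):
        if self.activation == "relu":
            d = _relu_backward(self, d)
        x = self._x
        kh, kw = self.kernel
        B, Ho, Wo, F = d.shape
        C = x.shape[-1]
        dW, db = self.grads
        db[:] = d.sum(axis=(0, 1, 2))
        d2 = np.ascontiguousarray(d).reshape(-1, F)
        dx = np.zeros_like(x) if self.needs_input_grad else None
        for i, j in product(range(kh), range(kw)):
            xs = np.ascontiguousarray(x[:, i : i + Ho, j : j + Wo, :]).reshape(-1, C)
            dW[i, j] = xs.T @ d2
            if dx is not None:
                dx[:, i : i + Ho, j : j + Wo, :] += (d2 @ self.W[i, j].T).reshape(
                    B, Ho, Wo, C
                )
        self._x = None
        return dx


class SeparableConv2D(_Layer):
    """Depthwise spatial convolution followed by a pointwise 1x1 projection."""

    def __init__(self, kernel, in_ch, filters, activation, rng):
        super().__init__()
        kh, kw = kernel
        self.Wd = rng.normal(0, np.sqrt(2.0 / (kh * kw)), (kh, kw, in_ch)).astype(_F)
        self.Wp = rng.normal(0, np.sqrt(2.0 / in_ch), (in_ch, filters)).astype(_F)
        self.b = np.zeros(filters, dtype=_F)
        self.kernel, self.activation = kernel, activation
        self.params = [self.Wd, self.Wp, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, training):
        kh, kw = self.kernel
        B, H, Wd_, C = x.shape
        Ho, Wo = H - kh + 1, Wd_ - kw + 1
        mid = np.zeros((B, Ho, Wo, C), dtype=_F)
        for i, j in product(range(kh), range(kw)):
            mid += x[:, i : i + Ho, j : j + Wo, :] * self.Wd[i, j]
        out = mid @ self.Wp + self.b
        self._x, self._mid = x, mid
        return _relu_forward(self, out) if self.activation == "relu" else out

    def backward(self, d):
        if self.activation == "relu":
            d = _relu_backward(self, d)
        x, mid = self._x, self._mid
        kh, kw = self.kernel
        B, Ho, Wo, C = mid.shape
        dWd, dWp, db = self.grads
        db[:] = d.sum(axis=(0, 1, 2))
        dWp[:] = np.tensordot(mid, d, axes=([0, 1, 2], [0, 1, 2]))
        dmid = d @ self.Wp.T
        dx = np.zeros_like(x)
        for i, j in product(range(kh), range(kw)):
            xs = x[:, i : i + Ho, j : j + Wo, :]
            dWd[i, j] = (xs * dmid).sum(axis=(0, 1, 2))
            dx[:, i : i + Ho, j : j + Wo, :] += dmid * self.Wd[i, j]
        self._x = self._mid = None
        return dx


class BatchNorm(_Layer):
    """Per-channel normalisation over batch and spatial axes."""

    def __init__(self, channels, momentum=0.9, eps=1e-5):
        super().__init__()
        self.gamma = np.ones(channels, dtype=_F)
        self.beta = np.zeros(channels, dtype=_F)
        self.running_mean = np.zeros(channels, dtype=_F)
        self.running_var = np.ones(channels, dtype=_F)
        self.momentum, self.eps = momentum, eps
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def forward(self, x, training):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean *= self.momentum
            self.running_mean += (1 - self.momentum) * mean
            self.running_var *= self.momentum
            self.running_var += (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if training:
            self._xhat, self._inv, self._axes = xhat, inv, axes
            self._n = x.size // x.shape[-1]
        return (self.gamma * xhat + self.beta).astype(_F)

    def backward(self, d):
        xhat, inv, axes, n = self._xhat, self._inv, self._axes, self._n
        dgamma, dbeta = self.grads
        dgamma[:] = (d * xhat).sum(axis=axes)
        dbeta[:] = d.sum(axis=axes)
        dxhat = d * self.gamma
        dx = (
            dxhat
            - dxhat.mean(axis=axes)
            - xhat * (dxhat * xhat).mean(axis=axes)
        ) * inv
        self._xhat = None
        return dx.astype(_F)


class _Pool(_Layer):
    """Non-overlapping pooling over the leading spatial/spectral axes."""

    def __init__(self, pool, mode):
        super().__init__()
        self.pool, self.mode = tuple(pool), mode

    def forward(self, x, training):
        p = self.pool
        nd = len(p)
        B = x.shape[0]
        C = x.shape[-1]
        dims = x.shape[1 : 1 + nd]
        out_dims = [dims[i] // p[i] for i in range(nd)]
        self._in_shape = x.shape
        # crop to a multiple of the window, then expose windows as one axis
        slicer = (slice(None),) + tuple(
            slice(0, out_dims[i] * p[i]) for i in range(nd)
        ) + (slice(None),)
        xc = x[slicer]
        shape = [B]
        for i in range(nd):
            shape += [out_dims[i], p[i]]
        shape += [C]
        xr = xc.reshape(shape)
        # bring window axes together: (B, out..., p0*p1*..., C)
        perm = [0] + [1 + 2 * i for i in range(nd)] + [2 + 2 * i for i in range(nd)] + [1 + 2 * nd]
        xr = xr.transpose(perm).reshape([B] + out_dims + [int(np.prod(p)), C])
        if self.mode == "max":
            self._arg = xr.argmax(axis=-2)
            out = np.take_along_axis(xr, self._arg[..., None, :], axis=-2)[..., 0, :]
        else:
            out = xr.mean(axis=-2)
        return out

    def backward(self, d):
        p = self.pool
        nd = len(p)
        B = d.shape[0]
        C = d.shape[-1]
        out_dims = list(d.shape[1 : 1 + nd])
        win = int(np.prod(p))
        dxr = np.zeros([B] + out_dims + [win, C], dtype=_F)
        if self.mode == "max":
            np.put_along_axis(dxr, self._arg[..., None, :], d[..., None, :], axis=-2)
        else:
            dxr[:] = (d / win)[..., None, :]
        # invert the transpose/reshape
        shape = [B] + [v for i in range(nd) for v in (out_dims[i], p[i])] + [C]
        perm = [0] + [1 + 2 * i for i in range(nd)] + [2 + 2 * i for i in range(nd)] + [1 + 2 * nd]
        inv_perm = np.argsort(perm)
        dxc = (
            dxr.reshape([B] + out_dims + list(p) + [C])
            .transpose(inv_perm)
            .reshape([B] + [out_dims[i] * p[i] for i in range(nd)] + [C])
        )
        dx = np.zeros(self._in_shape, dtype=_F)
        slicer = (slice(None),) + tuple(
            slice(0, out_dims[i] * p[i]) for i in range(nd)
        ) + (slice(None),)
        dx[slicer] = dxc
        return dx


class Reshape3D2D(_Layer):
    """Fold (depth x channels) into 2-D channels, band-major order."""

    def forward(self, x, training):
        self._in_shape = x.shape
        B, H, W, D, C = x.shape
        return np.ascontiguousarray(x).reshape(B, H, W, D * C)

    def backward(self, d):
        return d.reshape(self._in_shape)


class Flatten(_Layer):
    def forward(self, x, training):
        self._in_shape = x.shape
        return np.ascontiguousarray(x).reshape(x.shape[0], -1)

    def backward(self, d):
        return d.reshape(self._in_shape)


class Dense(_Layer):
    def __init__(self, in_units, units, activation, rng):
        super().__init__()
        if activation == "relu":
            scale = np.sqrt(2.0 / in_units)
        else:  # linear/softmax head: Glorot keeps initial logits small
            scale = np.sqrt(1.0 / in_units)
        self.W = rng.normal(0, scale, (in_units, units)).astype(_F)
        self.b = np.zeros(units, dtype=_F)
        self.activation = activation
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training):
        self._x = x
        z = x @ self.W + self.b
        return _relu_forward(self, z) if self.activation == "relu" else z

    def backward(self, d):
        if self.activation == "relu":
            d = _relu_backward(self, d)
        dW, db = self.grads
        dW[:] = self._x.T @ d
        db[:] = d.sum(axis=0)
        dx = d @ self.W.T
        self._x = None
        return dx


class Dropout(_Layer):
    def __init__(self, rate, rng):
        super().__init__()
        self.rate, self._rng = rate, rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self._rng.random(x.shape) < keep).astype(_F) / keep
        return x * self._mask

    def backward(self, d):
        return d if self._mask is None else d * self._mask


class Network:
    """Compiled stack of runtime layers for one :class:`ModelSpec`."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        from .spec import infer_shapes

        self.spec = spec
        rng = np.random.default_rng(seed)
        shapes = [tuple(spec.input_shape)] + infer_shapes(spec)
        self.layers = []
        for lspec, in_shape in zip(spec.layers, shapes[:-1]):
            k = lspec.kind
            if k == "conv3d":
                layer = Conv3D(lspec.kernel, in_shape[-1], lspec.filters,
                               lspec.activation, rng)
            elif k == "conv2d":
                layer = Conv2D(lspec.kernel, in_shape[-1], lspec.filters,
                               lspec.activation, rng)
            elif k == "sepconv2d":
                layer = SeparableConv2D(lspec.kernel, in_shape[-1], lspec.filters,
                                        lspec.activation, rng)
            elif k == "batchnorm":
                layer = BatchNorm(in_shape[-1])
            elif k == "maxpool3d":
                layer = _Pool(lspec.pool, "max")
            elif k == "maxpool2d":
                layer = _Pool(lspec.pool, "max")
            elif k == "avgpool2d":
                layer = _Pool(lspec.pool, "avg")
            elif k == "reshape3d2d":
                layer = Reshape3D2D()
            elif k == "flatten":
                layer = Flatten()
            elif k == "dense":
                layer = Dense(int(np.prod(in_shape)), lspec.units,
                              lspec.activation, rng)
            elif k == "dropout":
                layer = Dropout(lspec.rate, rng)
            elif k == "softmax":
                layer = _Layer()  # handled by the loss / predict
            else:
                raise InvalidInputError(f"unknown layer kind {k!r}")
            self.layers.append(layer)
        # the gradient w.r.t. the network input is never consumed
        if self.layers:
            self.layers[0].needs_input_grad = False

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x  # logits (softmax applied by loss / predict)

    def backward(self, dlogits):
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    def parameters(self):
        return [p for layer in self.layers for p in layer.params]

    def gradients(self):
        return [g for layer in self.layers for g in layer.grads]

    def get_weights(self):
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights):
        for p, w in zip(self.parameters(), weights):
            p[...] = w


def compile_network(spec: ModelSpec, seed: int = 0) -> Network:
    return Network(spec, seed)


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class TrainedModel:
    """A compiled network plus the label encoding and input statistics."""

    network: Network
    classes: np.ndarray
    mu: np.ndarray | None
    sd: np.ndarray | None
    config: TrainConfig
    history: dict = field(default_factory=dict)

    def save_weights(self, path: str) -> None:
        """Checkpoint: parameters + label encoding + input statistics."""
        arrays = {f"p{i}": p for i, p in enumerate(self.network.parameters())}
        arrays["classes"] = np.asarray(self.classes, dtype="U16")
        if self.mu is not None:
            arrays["mu"], arrays["sd"] = self.mu, self.sd
        np.savez(path, **arrays)

    def load_weights(self, path: str) -> None:
        with np.load(path) as data:
            params = self.network.parameters()
            for i, p in enumerate(params):
                p[...] = data[f"p{i}"]
            self.classes = data["classes"]
            if "mu" in data:
                self.mu, self.sd = data["mu"], data["sd"]

    def _prepare(self, X):
        X = np.asarray(X, dtype=_F)
        if self.mu is not None:
            # statistics are per spectral band = last axis of raw patch data
            if X.shape[-1] == self.mu.shape[0]:
                X = (X - self.mu) / self.sd
            elif X.ndim >= 2 and X.shape[-2] == self.mu.shape[0] and X.shape[-1] == 1:
                X = (X - self.mu[:, None]) / self.sd[:, None]
            else:
                raise InvalidInputError(
                    f"cannot align stored band statistics ({self.mu.shape[0]} "
                    f"bands) with input of shape {X.shape[1:]}"
                )
        want = len(self.network.spec.input_shape)
        if X.ndim == want and want == 4 and self.network.spec.input_shape[-1] == 1:
            X = X[..., None]  # (N, m, n, k) -> (N, m, n, k, 1) for 3-D nets
        if X.shape[1:] != tuple(self.network.spec.input_shape):
            raise InvalidInputError(
                f"input shape {X.shape[1:]} does not match model "
                f"{self.network.spec.input_shape}"
            )
        return X


def _band_stats(X):
    """Per-band mean/sd over samples and spatial axes (band = last data axis)."""
    axes = tuple(range(X.ndim - 1))
    mu = X.mean(axis=axes, dtype=np.float64).astype(_F)
    sd = X.std(axis=axes, dtype=np.float64).astype(_F)
    sd[sd == 0] = 1.0
    return mu, sd


def _encode_labels(y, classes):
    lut = {c: i for i, c in enumerate(classes)}
    return np.array([lut[v] for v in y], dtype=np.int64)


def train(
    spec: ModelSpec,
    X_train,
    y_train,
    X_val=None,
    y_val=None,
    config: TrainConfig | None = None,
) -> TrainedModel:
    """Train a network on labelled patches.

    Inputs are standardised per band using training statistics (stored with
    the model).  With validation data, the weights with the best validation
    accuracy are retained and early stopping applies after
    ``early_stopping_patience`` epochs without improvement.
    """
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)
    net = Network(spec, seed=int(rng.integers(2**31)))

    classes = np.unique(np.asarray(y_train))
    if classes.size != spec.n_classes:
        raise InvalidInputError(
            f"model expects {spec.n_classes} classes, labels have {classes.size}"
        )
    model = TrainedModel(net, classes, None, None, config)

    X = np.asarray(X_train, dtype=_F)
    if config.standardize_inputs:
        # stats computed on the raw band axis before any channel axis is added
        mu, sd = _band_stats(X)
        model.mu, model.sd = mu, sd
    X = model._prepare(X_train)
    y = _encode_labels(np.asarray(y_train), classes)
    if X_val is not None and len(X_val):
        Xv = model._prepare(X_val)
        yv = _encode_labels(np.asarray(y_val), classes)
    else:
        Xv = yv = None

    opt = Adam(net.parameters(), lr=config.learning_rate)
    history = {"loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []}
    best_val, best_weights, patience_left = -np.inf, None, config.early_stopping_patience
    n = X.shape[0]
    onehot = np.eye(spec.n_classes, dtype=_F)

    for epoch in range(config.epochs):
        order = rng.permutation(n) if config.shuffle else np.arange(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X[idx], y[idx]
            logits = net.forward(xb, training=True)
            probs = _softmax(logits.astype(np.float64))
            losses.append(
                -np.mean(np.log(np.clip(probs[np.arange(len(yb)), yb], 1e-12, None)))
            )
            correct += int((probs.argmax(axis=1) == yb).sum())
            dlogits = ((probs - onehot[yb]) / len(yb)).astype(_F)
            net.backward(dlogits)
            opt.step(net.parameters(), net.gradients())
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(correct / n)

        if Xv is not None:
            vl, va = _evaluate(net, Xv, yv, config.batch_size)
            history["val_loss"].append(vl)
            history["val_accuracy"].append(va)
            if va > best_val:
                best_val, best_weights = va, net.get_weights()
                patience_left = config.early_stopping_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break

    if best_weights is not None:
        net.set_weights(best_weights)
    model.history = history
    return model


def _evaluate(net, X, y, batch_size):
    losses, correct = [], 0
    for start in range(0, X.shape[0], batch_size):
        xb, yb = X[start : start + batch_size], y[start : start + batch_size]
        probs = _softmax(net.forward(xb, training=False).astype(np.float64))
        losses.append(
            -np.mean(np.log(np.clip(probs[np.arange(len(yb)), yb], 1e-12, None)))
        )
        correct += int((probs.argmax(axis=1) == yb).sum())
    return float(np.mean(losses)), correct / X.shape[0]


def predict(model: TrainedModel, X, batch_size: int = 128):
    """Class probabilities and labels for a batch of patches.

    Probabilities row-sum to 1; argmax ties resolve to the lowest class
    index.  Outputs are independent of ``batch_size``.
    """
    X = model._prepare(X)
    probs = np.concatenate(
        [
            _softmax(
                model.network.forward(X[s : s + batch_size], training=False).astype(
                    np.float64
                )
            )
            for s in range(0, X.shape[0], batch_size)
        ]
    )
    labels = model.classes[probs.argmax(axis=1)]
    return probs, labels
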