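"""Minimal CPU runtime for the declarative model graphs.

Materializes a :class:`~tumorkit.models.ModelGraph` into a runnable network
with explicit forward/backward passes in float32 numpy.  Convolutions are
im2col + BLAS matmul; transposed convolutions are implemented as
zero-dilation followed by a full correlation (their gradients reuse the same
machinery).  Supported layer kinds are exactly those the architecture
builders emit: conv (stride 1, same/valid), transposed conv (stride 2),
dense on the trailing axis, 1-D/2-D max pooling, batch normalization with
moving statistics, inverted dropout, flatten, concatenation and bare ReLU
activation blocks.

Everything is deterministic given the construction seed: weight
initialization and dropout masks are drawn from a single PCG64 generator in
graph order, so two runs with the same seed produce bit-identical histories.
"""

from __future__ import annotations

import json

import numpy as np

from .errors import ShapeError
from .models import LayerSpec, ModelGraph, infer_shapes

_BN_EPS = 1e-3


# ---------------------------------------------------------------------------
# conv primitives (stride-1 correlation; strided sampling where needed)
# ---------------------------------------------------------------------------

def _pad_hw(x, ph, pw):
    if ph or pw:
        return np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    return x


def _corr2d(x, W, pad):
    """Stride-1 correlation of (B,H,W,Cin) with (kh,kw,Cin,Cout); pad=(ph,pw).

    Shift-and-GEMM formulation: one full-volume matmul per kernel tap with
    shifted accumulation, avoiding any im2col patch materialization.
    """
    kh, kw, Cin, Cout = W.shape
    xp = _pad_hw(x, *pad)
    B, Hp, Wp, _ = xp.shape
    OH, OW = Hp - kh + 1, Wp - kw + 1
    xf = np.ascontiguousarray(xp).reshape(-1, Cin)
    if kh == 1 and kw == 1:
        return (xf @ W.reshape(Cin, Cout)).reshape(B, OH, OW, Cout)
    y = np.zeros((B, OH, OW, Cout), dtype=np.float32)
    buf = np.empty((B * Hp * Wp, Cout), dtype=np.float32)
    for a in range(kh):
        for b in range(kw):
            np.matmul(xf, W[a, b], out=buf)
            y += buf.reshape(B, Hp, Wp, Cout)[:, a:a + OH, b:b + OW, :]
    return y


def _corr2d_dw(x, dz, kh, kw, pad):
    """Weight gradient of _corr2d: embed dz at each tap offset and GEMM."""
    xp = _pad_hw(x, *pad)
    B, Hp, Wp, Cin = xp.shape
    OH, OW, Cout = dz.shape[1], dz.shape[2], dz.shape[3]
    xf = np.ascontiguousarray(xp).reshape(-1, Cin)
    if kh == 1 and kw == 1:
        return (xf.T @ dz.reshape(-1, Cout)).reshape(1, 1, Cin, Cout)
    dW = np.empty((kh, kw, Cin, Cout), dtype=np.float32)
    canvas = np.zeros((B, Hp, Wp, Cout), dtype=np.float32)
    for a in range(kh):
        for b in range(kw):
            canvas[:] = 0.0
            canvas[:, a:a + OH, b:b + OW, :] = dz
            dW[a, b] = xf.T @ canvas.reshape(-1, Cout)
    return dW


def _corr2d_dx(dz, W, pad, in_shape):
    """Input gradient of _corr2d (full correlation with the flipped kernel)."""
    kh, kw, Cin, Cout = W.shape
    Wf = np.ascontiguousarray(W[::-1, ::-1].transpose(0, 1, 3, 2))
    dxp = _corr2d(dz, Wf, pad=(kh - 1 - pad[0], kw - 1 - pad[1]))
    if dxp.shape[1:3] != in_shape[1:3]:
        raise ShapeError("conv backward shape mismatch")
    return dxp


def _apply_act(z, act):
    if act == "relu":
        return np.maximum(z, 0.0)
    if act == "sigmoid":
        # numerically stable logistic
        out = np.empty_like(z)
        pos = z >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
        ez = np.exp(z[~pos])
        out[~pos] = ez / (1.0 + ez)
        return out
    return z


def _act_grad(dout, y, act):
    if act == "relu":
        return dout * (y > 0)
    if act == "sigmoid":
        # clip away exact saturation so that, composed with the clipped BCE
        # gradient, the product reduces to the stable fused form (p - y)
        yc = np.clip(y, _CLIP, 1.0 - _CLIP)
        return dout * yc * (1.0 - yc)
    return dout


# ---------------------------------------------------------------------------
# runtime layers
# ---------------------------------------------------------------------------

def _glorot_uniform(rng, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape).astype(np.float32)


class _Layer:
    """Base runtime layer: ``params``/``grads`` dicts plus cached activations."""

    trainable_params = ()

    def __init__(self, spec: LayerSpec, in_shapes, rng):
        self.spec = spec
        self.name = spec.name
        self.params: dict = {}
        self.grads: dict = {}

    def forward(self, xs, training):
        raise NotImplementedError

    def backward(self, dout):
        raise NotImplementedError


class _Input(_Layer):
    def forward(self, xs, training):
        return xs[0]

    def backward(self, dout):
        return [dout]


class _Conv(_Layer):
    trainable_params = ("W", "b")

    def __init__(self, spec, in_shapes, rng):
        super().__init__(spec, in_shapes, rng)
        cin = in_shapes[0][-1]
        if len(spec.kernel) == 1:
            self._one_d = True
            kh, kw = spec.kernel[0], 1
        else:
            self._one_d = False
            kh, kw = spec.kernel
        self.params["W"] = _glorot_uniform(rng, (kh, kw, cin, spec.filters),
                                           kh * kw * cin, kh * kw * spec.filters)
        self.params["b"] = np.zeros(spec.filters, dtype=np.float32)
        self.pad = ((kh - 1) // 2, (kw - 1) // 2) if spec.padding == "same" else (0, 0)

    def _as4d(self, x):
        return x[:, :, None, :] if self._one_d else x

    def forward(self, xs, training):
        x = self._as4d(xs[0])
        self._x = x
        z = _corr2d(x, self.params["W"], self.pad) + self.params["b"]
        y = _apply_act(z, self.spec.activation)
        self._y = y
        return y[:, :, 0, :] if self._one_d else y

    def backward(self, dout):
        if self._one_d:
            dout = dout[:, :, None, :]
        dz = np.asarray(_act_grad(dout, self._y, self.spec.activation),
                        dtype=np.float32)
        kh, kw = self.params["W"].shape[:2]
        self.grads["b"] = dz.sum(axis=(0, 1, 2))
        self.grads["W"] = _corr2d_dw(self._x, dz, kh, kw, self.pad)
        dx = _corr2d_dx(dz, self.params["W"], self.pad, self._x.shape)
        self._x = self._y = None
        return [dx[:, :, 0, :] if self._one_d else dx]


class _TransposedConv(_Layer):
    """Transposed convolution, stride 2, output spatial size exactly doubled."""

    trainable_params = ("W", "b")

    def __init__(self, spec, in_shapes, rng):
        super().__init__(spec, in_shapes, rng)
        cin = in_shapes[0][-1]
        kh, kw = spec.kernel
        self.params["W"] = _glorot_uniform(rng, (kh, kw, cin, spec.filters),
                                           kh * kw * cin, kh * kw * spec.filters)
        self.params["b"] = np.zeros(spec.filters, dtype=np.float32)
        self.crop = (kh - 1) // 2

    def forward(self, xs, training):
        """Scatter formulation: ``full[2i + a, 2j + b] += x[i, j] @ W[a, b]``,
        then crop to the doubled spatial size."""
        x = np.ascontiguousarray(xs[0])
        self._x = x
        W = self.params["W"]
        k = self.spec.kernel[0]
        c = self.crop
        B, H, Wd, Cin = x.shape
        Cout = W.shape[-1]
        xf = x.reshape(-1, Cin)
        full = np.zeros((B, 2 * H + k - 2, 2 * Wd + k - 2, Cout), dtype=np.float32)
        buf = np.empty((B * H * Wd, Cout), dtype=np.float32)
        for a in range(k):
            for b in range(k):
                np.matmul(xf, W[a, b], out=buf)
                full[:, a:a + 2 * H:2, b:b + 2 * Wd:2, :] += buf.reshape(B, H, Wd, Cout)
        z = full[:, c:c + 2 * H, c:c + 2 * Wd, :] + self.params["b"]
        self._y = _apply_act(z, self.spec.activation)
        return self._y

    def backward(self, dout):
        x = self._x
        W = self.params["W"]
        k = self.spec.kernel[0]
        c = self.crop
        B, H, Wd, Cin = x.shape
        Cout = W.shape[-1]
        dz = np.asarray(_act_grad(dout, self._y, self.spec.activation),
                        dtype=np.float32)
        self.grads["b"] = dz.sum(axis=(0, 1, 2))
        dz_full = np.zeros((B, 2 * H + k - 2, 2 * Wd + k - 2, Cout), dtype=np.float32)
        dz_full[:, c:c + 2 * H, c:c + 2 * Wd, :] = dz
        xf = x.reshape(-1, Cin)
        dW = np.empty_like(W)
        dx = np.zeros((B * H * Wd, Cin), dtype=np.float32)
        for a in range(k):
            for b in range(k):
                S = np.ascontiguousarray(
                    dz_full[:, a:a + 2 * H:2, b:b + 2 * Wd:2, :]).reshape(-1, Cout)
                dW[a, b] = xf.T @ S
                dx += S @ W[a, b].T
        self.grads["W"] = dW
        self._x = self._y = None
        return [dx.reshape(B, H, Wd, Cin)]


class _Dense(_Layer):
    trainable_params = ("W", "b")

    def __init__(self, spec, in_shapes, rng):
        super().__init__(spec, in_shapes, rng)
        din = in_shapes[0][-1]
        self.params["W"] = _glorot_uniform(rng, (din, spec.units), din, spec.units)
        self.params["b"] = np.zeros(spec.units, dtype=np.float32)

    def forward(self, xs, training):
        self._x = xs[0]
        z = self._x @ self.params["W"] + self.params["b"]
        self._y = _apply_act(z, self.spec.activation)
        return self._y

    def backward(self, dout):
        dz = _act_grad(dout, self._y, self.spec.activation).astype(np.float32)
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dz2 = dz.reshape(-1, dz.shape[-1])
        self.grads["W"] = x2.T @ dz2
        self.grads["b"] = dz2.sum(axis=0)
        dx = dz @ self.params["W"].T
        self._x = self._y = None
        return [dx]


class _MaxPool(_Layer):
    def forward(self, xs, training):
        x = xs[0]
        self._in_shape = x.shape
        if len(self.spec.pool) == 1:
            p = self.spec.pool[0]
            B, L, C = x.shape
            L2 = (L // p) * p
            r = x[:, :L2].reshape(B, L2 // p, p, C)
            y = r.max(axis=2)
            self._mask = (r == y[:, :, None, :])
            return y
        B, H, W, C = x.shape
        H2, W2 = (H // 2) * 2, (W // 2) * 2
        r = x[:, :H2, :W2].reshape(B, H2 // 2, 2, W2 // 2, 2, C)
        y = r.max(axis=(2, 4))
        self._mask = (r == y[:, :, None, :, None, :])
        return y

    def backward(self, dout):
        dx = np.zeros(self._in_shape, dtype=np.float32)
        m = self._mask
        if len(self.spec.pool) == 1:
            p = self.spec.pool[0]
            counts = m.sum(axis=2, keepdims=True)
            dr = m * (dout[:, :, None, :] / counts)
            B, L, C = self._in_shape
            L2 = (L // p) * p
            dx[:, :L2] = dr.reshape(B, L2, C)
        else:
            counts = m.sum(axis=(2, 4), keepdims=True)
            dr = m * (dout[:, :, None, :, None, :] / counts)
            B, H, W, C = self._in_shape
            H2, W2 = (H // 2) * 2, (W // 2) * 2
            dx[:, :H2, :W2] = dr.reshape(B, H2, W2, C)
        self._mask = None
        return [dx]


class _BatchNorm(_Layer):
    """Channels-last batch normalization.

    ``gamma``/``beta`` are trainable; the moving mean/variance (updated with
    ``momentum * moving + (1 - momentum) * batch`` during training) are the
    non-trainable half of the parameter audit.
    """

    trainable_params = ("gamma", "beta")

    def __init__(self, spec, in_shapes, rng):
        super().__init__(spec, in_shapes, rng)
        c = in_shapes[0][-1]
        self.params["gamma"] = np.ones(c, dtype=np.float32)
        self.params["beta"] = np.zeros(c, dtype=np.float32)
        self.params["moving_mean"] = np.zeros(c, dtype=np.float32)
        self.params["moving_var"] = np.ones(c, dtype=np.float32)

    def forward(self, xs, training):
        x = xs[0]
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.spec.momentum
            self.params["moving_mean"] = (m * self.params["moving_mean"]
                                          + (1.0 - m) * mu).astype(np.float32)
            self.params["moving_var"] = (m * self.params["moving_var"]
                                         + (1.0 - m) * var).astype(np.float32)
        else:
            mu = self.params["moving_mean"]
            var = self.params["moving_var"]
        self._std = np.sqrt(var + _BN_EPS).astype(np.float32)
        self._xhat = ((x - mu) / self._std).astype(np.float32)
        self._training = training
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dout):
        axes = tuple(range(dout.ndim - 1))
        xhat = self._xhat
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        g = self.params["gamma"] / self._std
        if not self._training:
            return [dout * g]
        n = float(np.prod(dout.shape[:-1]))
        dxhat = dout * self.params["gamma"]
        dx = (dxhat - dxhat.mean(axis=axes)
              - xhat * (dxhat * xhat).mean(axis=axes)) / self._std
        self._xhat = None
        return [dx.astype(np.float32)]


class _Dropout(_Layer):
    def __init__(self, spec, in_shapes, rng):
        super().__init__(spec, in_shapes, rng)
        self._rng = rng

    def forward(self, xs, training):
        x = xs[0]
        if not training or self.spec.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.spec.rate
        self._mask = (self._rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return [dout]
        dx = dout * self._mask
        self._mask = None
        return [dx]


class _Flatten(_Layer):
    def forward(self, xs, training):
        self._shape = xs[0].shape
        return xs[0].reshape(xs[0].shape[0], -1)

    def backward(self, dout):
        return [dout.reshape(self._shape)]


class _Concat(_Layer):
    def forward(self, xs, training):
        self._splits = np.cumsum([x.shape[-1] for x in xs])[:-1]
        return np.concatenate(xs, axis=-1)

    def backward(self, dout):
        return list(np.split(dout, self._splits, axis=-1))


class _Activation(_Layer):
    def forward(self, xs, training):
        self._y = _apply_act(xs[0], self.spec.activation)
        return self._y

    def backward(self, dout):
        dx = _act_grad(dout, self._y, self.spec.activation)
        self._y = None
        return [dx]


_KINDS = {
    "input": _Input, "conv": _Conv, "transposed_conv": _TransposedConv,
    "dense": _Dense, "maxpool": _MaxPool, "batchnorm": _BatchNorm,
    "dropout": _Dropout, "flatten": _Flatten, "concat": _Concat,
    "activation": _Activation,
}


class Network:
    """Executable network compiled from a :class:`ModelGraph`."""

    def __init__(self, graph: ModelGraph, seed: int = 0):
        self.graph = graph
        self.rng = np.random.default_rng(seed)
        shapes = infer_shapes(graph)
        self.layers = []
        self._by_name = {}
        for spec in graph.layers:
            in_shapes = [shapes[n] for n in spec.inbound]
            layer = _KINDS[spec.kind](spec, in_shapes, self.rng)
            self.layers.append(layer)
            self._by_name[spec.name] = layer
        self.input_name = graph.layers[0].name
        self.output_name = graph.output_name
        # consumer map for backward accumulation
        self._consumers = {spec.name: [] for spec in graph.layers}
        for spec in graph.layers:
            for src in spec.inbound:
                self._consumers[src].append(spec.name)

    # -- execution ---------------------------------------------------------

    def forward(self, x, training: bool = False):
        x = np.asarray(x, dtype=np.float32)
        outs = {}
        for layer in self.layers:
            spec = layer.spec
            xs = [x] if spec.kind == "input" else [outs[n] for n in spec.inbound]
            outs[spec.name] = layer.forward(xs, training)
        self._outs_keys = list(outs)
        return outs[self.output_name]

    def backward(self, dout):
        grads = {self.output_name: np.asarray(dout, dtype=np.float32)}
        for layer in reversed(self.layers):
            spec = layer.spec
            g = grads.pop(spec.name, None)
            if g is None or spec.kind == "input":
                continue
            dins = layer.backward(g)
            for src, d in zip(spec.inbound, dins):
                if src in grads:
                    grads[src] = grads[src] + d
                else:
                    grads[src] = d

    def predict(self, X, batch_size: int = 8):
        """Evaluation-mode forward pass over a batch-of-samples array."""
        chunks = [self.forward(X[i:i + batch_size], training=False)
                  for i in range(0, len(X), batch_size)]
        return np.concatenate(chunks, axis=0)

    # -- parameter plumbing ------------------------------------------------

    def trainable(self):
        """Yield (key, layer, param_name) for every gradient-updated array."""
        for layer in self.layers:
            for p in layer.trainable_params:
                yield f"{layer.name}:{p}", layer, p

    # -- persistence -------------------------------------------------------

    def save(self, path):
        arrays = {"__graph__": np.frombuffer(
            json.dumps([vars(s) if not hasattr(s, "__dataclass_fields__") else
                        {k: getattr(s, k) for k in s.__dataclass_fields__}
                        for s in self.graph.layers]).encode(), dtype=np.uint8),
            "__name__": np.frombuffer(self.graph.name.encode(), dtype=np.uint8)}
        for layer in self.layers:
            for p, arr in layer.params.items():
                arrays[f"{layer.name}:{p}"] = arr
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "Network":
        data = np.load(path)
        specs = json.loads(bytes(data["__graph__"]).decode())
        layers = [LayerSpec(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in s.items()}) for s in specs]
        graph = ModelGraph(bytes(data["__name__"]).decode(), layers)
        net = cls(graph, seed=0)
        for layer in net.layers:
            for p in list(layer.params):
                key = f"{layer.name}:{p}"
                if key in data:
                    layer.params[p] = data[key].astype(np.float32)
        return net


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict = {}
        self.v: dict = {}

    def step(self, net: Network):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for key, layer, p in net.trainable():
            g = layer.grads.get(p)
            if g is None:
                continue
            m = self.m.setdefault(key, np.zeros_like(layer.params[p]))
            v = self.v.setdefault(key, np.zeros_like(layer.params[p]))
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            layer.params[p] -= (self.lr * (m / b1t)
                                / (np.sqrt(v / b2t) + self.eps)).astype(np.float32)


class RMSprop:
    def __init__(self, lr=1e-4, rho=0.9, eps=1e-7):
        self.lr, self.rho, self.eps = lr, rho, eps
        self.acc: dict = {}

    def step(self, net: Network):
        for key, layer, p in net.trainable():
            g = layer.grads.get(p)
            if g is None:
                continue
            a = self.acc.setdefault(key, np.zeros_like(layer.params[p]))
            a += (1.0 - self.rho) * (g * g - a)
            layer.params[p] -= (self.lr * g / (np.sqrt(a) + self.eps)).astype(np.float32)


def make_optimizer(name: str, lr: float):
    name = name.lower()
    if name == "adam":
        return Adam(lr=lr)
    if name == "rmsprop":
        return RMSprop(lr=lr)
    raise ValueError(f"unknown optimizer {name!r}")


# ---------------------------------------------------------------------------
# losses with gradients (training-side counterparts of models.dice/bce/hybrid)
# ---------------------------------------------------------------------------

_CLIP = 1e-7


def bce_with_grad(pred, truth):
    p = np.clip(pred, _CLIP, 1.0 - _CLIP)
    n = pred.size
    loss = float(np.mean(-(truth * np.log(p) + (1.0 - truth) * np.log(1.0 - p))))
    grad = ((p - truth) / (p * (1.0 - p))) / n
    return loss, grad.astype(np.float32)


def dice_with_grad(pred, truth):
    """Per-sample soft Dice loss averaged over the batch (axis 0)."""
    B = pred.shape[0]
    p = pred.reshape(B, -1).astype(np.float64)
    q = truth.reshape(B, -1).astype(np.float64)
    inter = (p * q).sum(axis=1)
    den = p.sum(axis=1) + q.sum(axis=1) + 1.0
    loss = float(np.mean(1.0 - (2.0 * inter + 1.0) / den))
    grad = -(2.0 * q * den[:, None] - (2.0 * inter + 1.0)[:, None]) / (den ** 2)[:, None] / B
    return loss, grad.reshape(pred.shape).astype(np.float32)


def hybrid_with_grad(pred, truth):
    l1, g1 = dice_with_grad(pred, truth)
    l2, g2 = bce_with_grad(pred, truth)
    return 0.5 * l1 + 0.5 * l2, 0.5 * g1 + 0.5 * g2


LOSSES = {"bce": bce_with_grad, "dice": dice_with_grad, "hybrid": hybrid_with_grad}
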