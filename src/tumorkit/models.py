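"""Network architectures, parameter audits, and loss functions.

Six binary-output architectures are described declaratively as :class:`ModelGraph`
objects — ordered lists of layer specifications with named inbound connections —
from which output shapes and parameter counts are derived by pure bookkeeping,
independently of any training runtime:

* an image-input tumor-detection CNN (256x256x3 input, two valid 8x8
  convolution blocks),
* a feature-input detection CNN (1-D convolution over a hand-crafted feature
  vector),
* a 2D U-Net and a 2D nested U-Net (U-Net++) for single-channel 128x128 slices,
* a multimodal U-Net and U-Net++ consuming four co-registered MRI contrasts
  (T1, T2, T1ce, FLAIR) as a 4-channel 128x128 input.

Parameter bookkeeping follows the standard conventions: a convolution with
``f`` filters over ``c`` input channels and kernel area ``k`` carries
``f*(k*c + 1)`` weights, a dense layer ``units*(inputs + 1)``, and batch
normalization ``4`` per channel of which the moving statistics (half) are
non-trainable.  Pooling, dropout, flatten, concatenation and bare activation
blocks carry none.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ShapeError

__all__ = [
    "LayerSpec",
    "ModelGraph",
    "ParamCount",
    "infer_shapes",
    "count_parameters",
    "build_detection_cnn",
    "build_feature_cnn",
    "build_unet2d",
    "build_unetpp2d",
    "build_unet_multimodal",
    "build_unetpp_multimodal",
    "dice_loss",
    "binary_cross_entropy",
    "hybrid_loss",
]

_EPS_CLIP = 1e-7


@dataclass(frozen=True)
class LayerSpec:
    """One node of a model graph.

    ``kind`` is one of ``input``, ``conv``, ``transposed_conv``, ``dense``,
    ``maxpool``, ``batchnorm``, ``dropout``, ``flatten``, ``concat``,
    ``activation``.  Shapes are channels-last: ``(H, W, C)`` for rasters and
    ``(L, C)`` for 1-D feature maps.
    """

    name: str
    kind: str
    inbound: tuple = ()
    filters: int = 0          # conv / transposed_conv
    units: int = 0            # dense (applied to the trailing axis)
    kernel: tuple = ()        # conv kernel, e.g. (3, 3) or (2,)
    stride: tuple = ()        # transposed_conv upsampling stride
    padding: str = "same"     # conv padding: "same" | "valid"
    activation: str = ""      # "" | "relu" | "sigmoid"
    rate: float = 0.0         # dropout rate
    momentum: float = 0.0     # batchnorm moving-average momentum
    pool: tuple = ()          # maxpool window
    shape: tuple = ()         # input shape


@dataclass
class ModelGraph:
    """Ordered, acyclic layer list; layer order is a topological order."""

    name: str
    layers: list = field(default_factory=list)

    def layer(self, name: str) -> LayerSpec:
        for spec in self.layers:
            if spec.name == name:
                return spec
        raise KeyError(name)

    @property
    def output_name(self) -> str:
        return self.layers[-1].name

    def to_json(self) -> str:
        """Audit export: layer list with inferred shapes and per-layer counts."""
        shapes = infer_shapes(self)
        rows = []
        for spec in self.layers:
            total, non_tr = _layer_params(spec, shapes)
            row = asdict(spec)
            row["output_shape"] = list(shapes[spec.name])
            row["params"] = total
            row["non_trainable_params"] = non_tr
            rows.append(row)
        return json.dumps({"name": self.name, "layers": rows}, indent=1)


@dataclass(frozen=True)
class ParamCount:
    total: int
    trainable: int
    non_trainable: int


class _GraphBuilder:
    """Small helper to assemble sequential-with-skips graphs."""

    def __init__(self, name: str):
        self.graph = ModelGraph(name)
        self._prev = None

    def add(self, kind: str, name: str, inbound=None, **kw) -> str:
        if inbound is None:
            inbound = (self._prev,) if self._prev else ()
        elif isinstance(inbound, str):
            inbound = (inbound,)
        else:
            inbound = tuple(inbound)
        self.graph.layers.append(LayerSpec(name=name, kind=kind, inbound=inbound, **kw))
        self._prev = name
        return name


def infer_shapes(graph: ModelGraph) -> dict:
    """Propagate output shapes through the graph (channels-last)."""
    shapes: dict = {}
    for spec in graph.layers:
        ins = [shapes[n] for n in spec.inbound]
        shapes[spec.name] = _infer_one(spec, ins)
    return shapes


def _infer_one(spec: LayerSpec, ins: list) -> tuple:
    kind = spec.kind
    if kind == "input":
        return tuple(spec.shape)
    if kind == "conv":
        (s,) = ins
        spatial, _ = s[:-1], s[-1]
        if spec.padding == "valid":
            spatial = tuple(d - k + 1 for d, k in zip(spatial, spec.kernel))
            if any(d <= 0 for d in spatial):
                raise ShapeError(f"{spec.name}: kernel {spec.kernel} larger than input {s}")
        return spatial + (spec.filters,)
    if kind == "transposed_conv":
        (s,) = ins
        spatial = tuple(d * st for d, st in zip(s[:-1], spec.stride))
        return spatial + (spec.filters,)
    if kind == "dense":
        (s,) = ins
        return s[:-1] + (spec.units,)
    if kind == "maxpool":
        (s,) = ins
        spatial = tuple(d // p for d, p in zip(s[:-1], spec.pool))
        if any(d <= 0 for d in spatial):
            raise ShapeError(f"{spec.name}: pooling collapses shape {s}")
        return spatial + (s[-1],)
    if kind == "flatten":
        (s,) = ins
        return (int(np.prod(s)),)
    if kind == "concat":
        spatial = ins[0][:-1]
        for s in ins[1:]:
            if s[:-1] != spatial:
                raise ShapeError(f"{spec.name}: concat spatial mismatch {ins}")
        return spatial + (sum(s[-1] for s in ins),)
    if kind in ("batchnorm", "dropout", "activation"):
        (s,) = ins
        return s
    raise ShapeError(f"unknown layer kind {kind!r}")


def _layer_params(spec: LayerSpec, shapes: dict):
    """(total, non_trainable) for one layer."""
    if spec.kind in ("conv", "transposed_conv"):
        in_ch = shapes[spec.inbound[0]][-1]
        k_area = int(np.prod(spec.kernel))
        return spec.filters * (k_area * in_ch + 1), 0
    if spec.kind == "dense":
        in_last = shapes[spec.inbound[0]][-1]
        return spec.units * (in_last + 1), 0
    if spec.kind == "batchnorm":
        c = shapes[spec.inbound[0]][-1]
        return 4 * c, 2 * c
    return 0, 0


def count_parameters(model: ModelGraph) -> ParamCount:
    """Audit a model graph: total / trainable / non-trainable parameters."""
    shapes = infer_shapes(model)
    total = non_tr = 0
    for spec in model.layers:
        t, n = _layer_params(spec, shapes)
        total += t
        non_tr += n
    return ParamCount(total=total, trainable=total - non_tr, non_trainable=non_tr)


def _scale(filters: int, width_multiplier: float) -> int:
    return max(1, int(round(filters * width_multiplier)))


# ---------------------------------------------------------------------------
# Detection architectures
# ---------------------------------------------------------------------------

def build_detection_cnn(width_multiplier: float = 1.0) -> ModelGraph:
    """Image-input tumor detection CNN.

    Input 256x256x3; two valid 8x8 convolution blocks (32 then 64 filters,
    ReLU) each followed by a parameter-free activation block, 2x2 max pooling
    and 0.2 dropout; flatten; single sigmoid output unit.  The intermediate
    "dense" rows of the published layer table carry no weights in the printed
    total (352,609), so they are realized as bare activation blocks.
    """
    b = _GraphBuilder("detection_cnn")
    w = width_multiplier
    b.add("input", "in", shape=(256, 256, 3))
    b.add("conv", "conv1", filters=_scale(32, w), kernel=(8, 8), padding="valid",
          activation="relu")
    b.add("activation", "act1", activation="relu")
    b.add("maxpool", "pool1", pool=(2, 2))
    b.add("dropout", "drop1", rate=0.2)
    b.add("conv", "conv2", filters=_scale(64, w), kernel=(8, 8), padding="valid",
          activation="relu")
    b.add("activation", "act2", activation="relu")
    b.add("maxpool", "pool2", pool=(2, 2))
    b.add("dropout", "drop2", rate=0.2)
    b.add("flatten", "flat")
    b.add("dense", "out", units=1, activation="sigmoid")
    return b.graph


def build_feature_cnn(n_features: int, width_multiplier: float = 1.0) -> ModelGraph:
    """Feature-input detection CNN over an ``(n_features, 1)`` vector.

    1-D convolution (64 filters, kernel 2, valid), dense 32, dropout 0.2,
    dense 16, max-pool 2, flatten, sigmoid unit.  With the 4-element intensity
    block this reproduces the printed 2,817 parameters.
    """
    if n_features < 2:
        raise ShapeError("feature CNN needs at least 2 features (valid kernel-2 conv)")
    b = _GraphBuilder("feature_cnn")
    w = width_multiplier
    b.add("input", "in", shape=(n_features, 1))
    b.add("conv", "conv1", filters=_scale(64, w), kernel=(2,), padding="valid",
          activation="relu")
    b.add("dense", "dense1", units=_scale(32, w), activation="relu")
    b.add("dropout", "drop1", rate=0.2)
    b.add("dense", "dense2", units=_scale(16, w), activation="relu")
    b.add("maxpool", "pool1", pool=(2,))
    b.add("flatten", "flat")
    b.add("dense", "out", units=1, activation="sigmoid")
    return b.graph


# ---------------------------------------------------------------------------
# Segmentation architectures
# ---------------------------------------------------------------------------

_ENCODER_FILTERS = (64, 128, 256, 512)


def _unet_encoder(b: _GraphBuilder, w: float):
    """Shared single-modality encoder: per level two 3x3 same conv (ReLU),
    2x2 max pool, batchnorm (momentum 0.8), dropout 0.1.  Returns the list of
    pre-pool conv outputs (skip sources) and the final pooled tensor name."""
    skips = []
    for i, f in enumerate(_ENCODER_FILTERS):
        fs = _scale(f, w)
        b.add("conv", f"enc{i}a", filters=fs, kernel=(3, 3), activation="relu")
        skips.append(b.add("conv", f"enc{i}b", filters=fs, kernel=(3, 3), activation="relu"))
        b.add("maxpool", f"pool{i}", pool=(2, 2))
        b.add("batchnorm", f"bn{i}", momentum=0.8)
        deepest = b.add("dropout", f"encdrop{i}", rate=0.1)
    return skips, deepest


def build_unet2d(width_multiplier: float = 1.0) -> ModelGraph:
    """2D U-Net for 128x128 single-channel slices.

    Encoder filters 64/128/256/512 with batchnorm + dropout, 512-filter
    bridge, transposed-conv (3x3, stride 2) decoder with skip concatenations
    and 0.1 dropout, 1x1 sigmoid head.  Audit: 22,718,529 parameters of which
    1,920 (the four encoder batchnorms' moving statistics) are non-trainable.
    """
    b = _GraphBuilder("unet2d")
    w = width_multiplier
    b.add("input", "in", shape=(128, 128, 1))
    skips, x = _unet_encoder(b, w)
    fb = _scale(512, w)
    b.add("conv", "bridge_a", filters=fb, kernel=(3, 3), activation="relu")
    b.add("conv", "bridge_b", filters=fb, kernel=(3, 3), activation="relu")
    for i, f in enumerate((512, 256, 128, 64)):
        fs = _scale(f, w)
        up = b.add("transposed_conv", f"up{i}", filters=fs, kernel=(3, 3), stride=(2, 2))
        b.add("concat", f"cat{i}", inbound=(up, skips[3 - i]))
        b.add("dropout", f"decdrop{i}", rate=0.1)
        b.add("conv", f"dec{i}a", filters=fs, kernel=(3, 3), activation="relu")
        b.add("conv", f"dec{i}b", filters=fs, kernel=(3, 3), activation="relu")
    b.add("conv", "out", filters=1, kernel=(1, 1), activation="sigmoid")
    return b.graph


def _build_unetpp(in_channels: int, width_multiplier: float, name: str) -> ModelGraph:
    """Nested U-Net (U-Net++) over a 128x128 input.

    Dense skip pathways: node ``X[i][j]`` (row i = resolution level, column j)
    receives an up-transition (transposed conv 3x3, stride 2, output channels
    equal to the node width) from ``X[i+1][j-1]`` concatenated with every
    earlier same-row node output.  Node widths per row: 64 / 128 / 256 / 256.
    Node X02 additionally concatenates the *reused* up-sampled tensor feeding
    X01 (a fresh up-transition there would add 73,792 parameters and break the
    audited total of 22,498,881).  The head concatenates the four row-0 node
    outputs into a 1x1 sigmoid convolution.
    """
    b = _GraphBuilder(name)
    w = width_multiplier
    b.add("input", "in", shape=(128, 128, in_channels))
    skips, x = _unet_encoder(b, w)  # X00..X30 pre-pool outputs
    fb = _scale(512, w)
    b.add("conv", "bridge_a", filters=fb, kernel=(3, 3), activation="relu")
    bridge = b.add("conv", "bridge_b", filters=fb, kernel=(3, 3), activation="relu")

    # node[(i, j)] -> output tensor name; column 0 is the encoder backbone
    node = {(0, 0): skips[0], (1, 0): skips[1], (2, 0): skips[2], (3, 0): skips[3],
            (4, 0): bridge}
    width = {0: _scale(64, w), 1: _scale(128, w), 2: _scale(256, w), 3: _scale(256, w)}
    up_of = {}

    for j in range(1, 5):
        for i in range(0, 4 - j + 1):
            if i > 3:
                continue
            src = node[(i + 1, j - 1)]
            up = b.add("transposed_conv", f"up{i}{j}", inbound=src,
                       filters=width[i], kernel=(3, 3), stride=(2, 2))
            up_of[(i, j)] = up
            parts = [up]
            if (i, j) == (0, 2):
                parts.append(up_of[(0, 1)])  # reused tensor, no new weights
            parts += [node[(i, k)] for k in range(j - 1, -1, -1)]
            b.add("concat", f"cat{i}{j}", inbound=parts)
            b.add("dropout", f"drop{i}{j}", rate=0.1)
            b.add("conv", f"x{i}{j}a", filters=width[i], kernel=(3, 3), activation="relu")
            node[(i, j)] = b.add("conv", f"x{i}{j}b", filters=width[i], kernel=(3, 3),
                                 activation="relu")

    b.add("concat", "head_cat", inbound=[node[(0, j)] for j in range(1, 5)])
    b.add("conv", "out", filters=1, kernel=(1, 1), activation="sigmoid")
    return b.graph


def build_unetpp2d(width_multiplier: float = 1.0) -> ModelGraph:
    """2D U-Net++ for 128x128 single-channel slices (audit: 22,498,881)."""
    return _build_unetpp(1, width_multiplier, "unetpp2d")


def build_unet_multimodal(width_multiplier: float = 1.0) -> ModelGraph:
    """Multimodal U-Net over 4-channel (T1, T2, T1ce, FLAIR) 128x128 input.

    Per encoder level two [3x3 conv -> batchnorm] blocks then 2x2 max pool;
    1024-filter bridge with batchnorm; decoder transposed conv 2x2 stride 2,
    skip concatenation, two [conv -> batchnorm] blocks; 1x1 sigmoid head.
    Audit: 31,055,873 parameters, 11,776 non-trainable (18 batchnorm layers).
    """
    b = _GraphBuilder("unet_multimodal")
    w = width_multiplier
    b.add("input", "in", shape=(128, 128, 4))
    skips = []
    for i, f in enumerate(_ENCODER_FILTERS):
        fs = _scale(f, w)
        b.add("conv", f"enc{i}a", filters=fs, kernel=(3, 3), activation="relu")
        b.add("batchnorm", f"bn{i}a", momentum=0.8)
        b.add("conv", f"enc{i}b", filters=fs, kernel=(3, 3), activation="relu")
        skips.append(b.add("batchnorm", f"bn{i}b", momentum=0.8))
        b.add("maxpool", f"pool{i}", pool=(2, 2))
    fb = _scale(1024, w)
    b.add("conv", "bridge_a", filters=fb, kernel=(3, 3), activation="relu")
    b.add("batchnorm", "bn_bridge_a", momentum=0.8)
    b.add("conv", "bridge_b", filters=fb, kernel=(3, 3), activation="relu")
    b.add("batchnorm", "bn_bridge_b", momentum=0.8)
    for i, f in enumerate((512, 256, 128, 64)):
        fs = _scale(f, w)
        up = b.add("transposed_conv", f"up{i}", filters=fs, kernel=(2, 2), stride=(2, 2))
        b.add("concat", f"cat{i}", inbound=(up, skips[3 - i]))
        b.add("conv", f"dec{i}a", filters=fs, kernel=(3, 3), activation="relu")
        b.add("batchnorm", f"dbn{i}a", momentum=0.8)
        b.add("conv", f"dec{i}b", filters=fs, kernel=(3, 3), activation="relu")
        b.add("batchnorm", f"dbn{i}b", momentum=0.8)
    b.add("conv", "out", filters=1, kernel=(1, 1), activation="sigmoid")
    return b.graph


def build_unetpp_multimodal(width_multiplier: float = 1.0) -> ModelGraph:
    """Multimodal U-Net++ (4-channel input, same nested topology as the 2D
    variant, 512-filter bridge, 128x128x1 sigmoid output)."""
    return _build_unetpp(4, width_multiplier, "unetpp_multimodal")


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def dice_loss(pred, truth) -> float:
    """Soft Dice loss ``1 - (2*sum(p*q) + 1) / (sum(p) + sum(q) + 1)``.

    The +1 smoothing makes the empty/empty case a perfect score (loss 0).
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ShapeError(f"prediction {pred.shape} vs truth {truth.shape}")
    inter = float((pred * truth).sum())
    return 1.0 - (2.0 * inter + 1.0) / (float(pred.sum()) + float(truth.sum()) + 1.0)


def binary_cross_entropy(pred, truth) -> float:
    """Pixel-mean binary cross-entropy with probabilities clipped to
    ``[1e-7, 1 - 1e-7]``."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ShapeError(f"prediction {pred.shape} vs truth {truth.shape}")
    p = np.clip(pred, _EPS_CLIP, 1.0 - _EPS_CLIP)
    return float(np.mean(-(truth * np.log(p) + (1.0 - truth) * np.log(1.0 - p))))


def hybrid_loss(pred, truth) -> float:
    """Equal-weight sum: ``0.5 * dice_loss + 0.5 * binary_cross_entropy``."""
    return 0.5 * dice_loss(pred, truth) + 0.5 * binary_cross_entropy(pred, truth)
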