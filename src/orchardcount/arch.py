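"""Declarative YOLOv5-v1 computation graph with exact parameter accounting.

The detector backbone/neck is described as an ordered list of
:class:`LayerSpec` nodes rather than a framework module, so the parameter
count is an analytic closed form and shape plumbing is validated without
instantiating weights.  A numpy forward pass (:func:`predict`) supports
untrained or externally supplied weights for shape and contract testing; no
training is implemented.

Structural features of the v1 variant:

* the focus stem slices the input into four 2x2 parity sub-images
  concatenated channel-wise (lossless space-to-depth), followed by a
  32-kernel conv + batch norm + Hardswish;
* BottleneckCSP-v1 blocks drop the transition convolution that the original
  block applied to the transformed path before concatenation, saving exactly
  ``hidden_channels**2`` parameters per block;
* squeeze-and-excitation (SE) channel attention in the backbone and neck;
* cross-path merges routed as layer 5 -> 18, 8 -> 14 and 13 -> 24, with the
  outputs of layers 14 and 21 combined (at layer 22) and layer 23 feeding the
  medium-object head.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit as _sigmoid

from .boxes import ANCHOR_TABLE, BoundingBox, iou_matrix

__all__ = [
    "LayerSpec",
    "ArchGraph",
    "LAYER_KINDS",
    "build_yolov5v1",
    "count_parameters",
    "layer_parameters",
    "csp_v1_parameters",
    "csp_original_parameters",
    "focus_transform",
    "init_weights",
    "forward",
    "predict",
    "nms",
    "summary",
    "graph_to_json",
]

LAYER_KINDS = frozenset({
    "conv", "batch_norm", "activation", "focus", "bottleneck_csp_v1",
    "se_block", "upsample", "concat", "detect_head",
})

DEFAULT_SE_REDUCTION = 4
DEFAULT_NMS_IOU = 0.45
DEFAULT_CONF_THRESHOLD = 0.5


@dataclass
class LayerSpec:
    """One node of the architecture graph.

    ``inputs`` reference strictly earlier indices (acyclic by construction);
    ``rescale`` (concat only) aligns input scales: +2 nearest-upsamples the
    input by two, -2 average-pools it by two, 1 leaves it unchanged.
    """

    index: int
    kind: str
    in_channels: int
    out_channels: int
    kernel: int = 1
    stride: int = 1
    inputs: tuple[int, ...] = ()
    repeats: int = 1                      # bottleneck count in CSP blocks
    reduction: int = DEFAULT_SE_REDUCTION  # SE squeeze ratio
    rescale: tuple[int, ...] = ()         # per-input scale alignment (concat)
    head_stride: int | None = None        # detect heads only
    note: str = ""

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if any(i >= self.index for i in self.inputs):
            raise ValueError(f"layer {self.index}: inputs must be earlier layers")


@dataclass
class ArchGraph:
    """Ordered layer list plus declared skip merges and per-head anchors."""

    layers: list[LayerSpec]
    merges: tuple[tuple[int, int], ...]
    anchor_config: dict[int, tuple[tuple[float, float], ...]]  # stride -> anchors
    num_classes: int = 1
    input_size: int = 640

    def layer(self, index: int) -> LayerSpec:
        return self.layers[index]

    @property
    def heads(self) -> list[LayerSpec]:
        return [l for l in self.layers if l.kind == "detect_head"]

    def validate(self) -> None:
        """Check acyclicity, channel plumbing and scale consistency.

        Raises ``ValueError`` naming the offending layer.
        """
        scales: dict[int, int] = {}
        for i, l in enumerate(self.layers):
            if l.index != i:
                raise ValueError(f"layer {i}: index field mismatch ({l.index})")
            srcs = l.inputs
            if l.kind == "focus":
                if srcs:
                    raise ValueError(f"layer {i}: focus reads the input image")
                scales[i] = 2
                continue
            if not srcs:
                raise ValueError(f"layer {i}: missing inputs")
            if l.kind == "concat":
                rescale = l.rescale or (1,) * len(srcs)
                if len(rescale) != len(srcs):
                    raise ValueError(f"layer {i}: rescale/inputs length mismatch")
                eff = []
                for s, r in zip(srcs, rescale):
                    sc = scales[s]
                    if r == 2:
                        sc //= 2
                    elif r == -2:
                        sc *= 2
                    elif r != 1:
                        raise ValueError(f"layer {i}: unsupported rescale {r}")
                    eff.append(sc)
                if len(set(eff)) != 1:
                    raise ValueError(f"layer {i}: concat inputs at mismatched scales {eff}")
                if sum(self.layers[s].out_channels for s in srcs) != l.out_channels:
                    raise ValueError(f"layer {i}: concat channel sum mismatch")
                scales[i] = eff[0]
                continue
            if len(srcs) != 1:
                raise ValueError(f"layer {i}: {l.kind} takes exactly one input")
            src = self.layers[srcs[0]]
            if src.out_channels != l.in_channels:
                raise ValueError(
                    f"layer {i}: expects {l.in_channels} channels, "
                    f"layer {srcs[0]} provides {src.out_channels}")
            sc = scales[srcs[0]]
            if l.kind == "conv":
                scales[i] = sc * l.stride
            elif l.kind == "upsample":
                scales[i] = sc // 2
            else:
                scales[i] = sc
            if l.kind == "detect_head":
                if l.head_stride != sc:
                    raise ValueError(
                        f"layer {i}: head stride {l.head_stride} != feature scale {sc}")
        for s, t in self.merges:
            if s not in self.layers[t].inputs:
                raise ValueError(f"declared merge {s}->{t} not realized by layer {t}")


# --------------------------------------------------------------------------
# parameter accounting (analytic closed forms)

def _conv_bn_params(ci: int, co: int, k: int) -> int:
    # convs followed by BN carry no bias; BN has 2*C learnable parameters
    return ci * co * k * k + 2 * co


def csp_v1_parameters(c1: int, c2: int, n: int) -> int:
    """BottleneckCSP-v1: transition conv on the transformed path removed."""
    c_ = c2 // 2
    p = _conv_bn_params(c1, c_, 1)                      # cv1
    p += n * (_conv_bn_params(c_, c_, 1) + _conv_bn_params(c_, c_, 3))
    p += c1 * c_                                        # shortcut 1x1, no bias
    p += 2 * (2 * c_)                                   # BN over the concat
    p += _conv_bn_params(2 * c_, c2, 1)                 # cv4
    return p


def csp_original_parameters(c1: int, c2: int, n: int) -> int:
    """Original BottleneckCSP with the extra transition convolution."""
    c_ = c2 // 2
    return csp_v1_parameters(c1, c2, n) + c_ * c_


def se_parameters(c: int, reduction: int) -> int:
    h = c // reduction
    return c * h + h + h * c + c


def layer_parameters(l: LayerSpec) -> int:
    if l.kind in ("conv", "focus"):
        return _conv_bn_params(l.in_channels, l.out_channels, l.kernel)
    if l.kind == "bottleneck_csp_v1":
        return csp_v1_parameters(l.in_channels, l.out_channels, l.repeats)
    if l.kind == "se_block":
        return se_parameters(l.in_channels, l.reduction)
    if l.kind == "batch_norm":
        return 2 * l.out_channels
    if l.kind == "detect_head":
        return l.in_channels * l.out_channels + l.out_channels  # 1x1 conv with bias
    return 0  # activation, upsample, concat


def count_parameters(graph: ArchGraph) -> int:
    """Total trainable parameters of the graph (analytic sum)."""
    graph.validate()
    return sum(layer_parameters(l) for l in graph.layers)


# --------------------------------------------------------------------------
# graph construction

def build_yolov5v1(input_size: int = 640, num_classes: int = 1,
                   se_reduction: int = DEFAULT_SE_REDUCTION) -> ArchGraph:
    """Build the default v1 detection graph.

    Three heads at strides 8/16/32 predict ``3 * (5 + num_classes)`` channels
    per cell using the retuned small/medium anchor tables.  The graph
    validates on construction.
    """
    if input_size % 32 != 0:
        raise ValueError("input_size must be a multiple of 32")
    no = 3 * (5 + num_classes)
    L = LayerSpec
    layers = [
        # backbone
        L(0, "focus", 12, 32, kernel=3, note="space-to-depth stem"),
        L(1, "conv", 32, 64, kernel=3, stride=2, inputs=(0,)),
        L(2, "bottleneck_csp_v1", 64, 64, inputs=(1,), repeats=1),
        L(3, "conv", 64, 128, kernel=3, stride=2, inputs=(2,)),
        L(4, "bottleneck_csp_v1", 128, 128, inputs=(3,), repeats=3),
        L(5, "conv", 128, 128, kernel=3, inputs=(4,), note="P3 lateral -> 18"),
        L(6, "conv", 128, 256, kernel=3, stride=2, inputs=(5,)),
        L(7, "bottleneck_csp_v1", 256, 256, inputs=(6,), repeats=3),
        L(8, "se_block", 256, 256, inputs=(7,), reduction=se_reduction,
          note="P4 lateral -> 14"),
        L(9, "conv", 256, 512, kernel=3, stride=2, inputs=(8,)),
        L(10, "bottleneck_csp_v1", 512, 512, inputs=(9,), repeats=1),
        L(11, "se_block", 512, 512, inputs=(10,), reduction=se_reduction),
        # neck
        L(12, "conv", 512, 256, kernel=1, inputs=(11,)),
        L(13, "bottleneck_csp_v1", 256, 256, inputs=(12,), repeats=1,
          note="P5 lateral -> 24"),
        L(14, "concat", 0, 512, inputs=(13, 8), rescale=(2, 1),
          note="merge 8 -> 14 (13 upsampled)"),
        L(15, "bottleneck_csp_v1", 512, 256, inputs=(14,), repeats=1),
        L(16, "conv", 256, 128, kernel=1, inputs=(15,)),
        L(17, "upsample", 128, 128, inputs=(16,)),
        L(18, "concat", 0, 256, inputs=(17, 5), note="merge 5 -> 18"),
        L(19, "bottleneck_csp_v1", 256, 128, inputs=(18,), repeats=1,
          note="small-object trunk"),
        L(20, "conv", 128, 128, kernel=3, stride=2, inputs=(19,)),
        L(21, "se_block", 128, 128, inputs=(20,), reduction=se_reduction),
        L(22, "concat", 0, 640, inputs=(21, 14), note="combine 14 and 21"),
        L(23, "bottleneck_csp_v1", 640, 256, inputs=(22,), repeats=1,
          note="medium-object trunk"),
        L(24, "concat", 0, 512, inputs=(23, 13), rescale=(-2, 1),
          note="merge 13 -> 24 (23 pooled)"),
        L(25, "bottleneck_csp_v1", 512, 512, inputs=(24,), repeats=1,
          note="large-object trunk"),
        # heads
        L(26, "detect_head", 128, no, inputs=(19,), head_stride=8),
        L(27, "detect_head", 256, no, inputs=(23,), head_stride=16),
        L(28, "detect_head", 512, no, inputs=(25,), head_stride=32),
    ]
    anchors = {
        stride: tuple(
            tuple(map(float, ANCHOR_TABLE[scale][m]))
            for scale in ("small", "medium", "large"))
        for m, stride in enumerate((8, 16, 32))
    }
    graph = ArchGraph(layers=layers, merges=((5, 18), (8, 14), (13, 24)),
                      anchor_config=anchors, num_classes=num_classes,
                      input_size=input_size)
    graph.validate()
    # structural contract of the v1 layout
    assert 14 in graph.layer(22).inputs and 21 in graph.layer(22).inputs
    assert graph.layer(27).inputs == (23,)
    assert len(graph.heads) == 3
    return graph


# --------------------------------------------------------------------------
# numpy inference

def focus_transform(image: np.ndarray) -> np.ndarray:
    """Lossless 2x2 space-to-depth slicing: (H, W, C) -> (H/2, W/2, 4C).

    Output channel ``c`` holds input channel ``c % C`` sampled at the parity
    slice ``c // C`` in the order (0,0), (1,0), (0,1), (1,1) of (row, col)
    offsets.  Pixels are a permutation of the input.
    """
    img = np.asarray(image)
    if img.ndim == 2:
        img = img[:, :, None]
    h, w, _ = img.shape
    if h % 2 or w % 2:
        raise ValueError("focus_transform requires even image dimensions")
    slices = [img[0::2, 0::2], img[1::2, 0::2], img[0::2, 1::2], img[1::2, 1::2]]
    return np.concatenate(slices, axis=-1)


def _hardswish(x: np.ndarray) -> np.ndarray:
    return x * np.clip(x + 3.0, 0.0, 6.0) / 6.0


def _conv2d(x: np.ndarray, w: np.ndarray, stride: int = 1,
            bias: np.ndarray | None = None) -> np.ndarray:
    """'same'-padded conv over (C, H, W) input via im2col + matmul."""
    co, ci, k, _ = w.shape
    pad = k // 2
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    c, h, wd = x.shape
    oh = (h - k) // stride + 1
    ow = (wd - k) // stride + 1
    sv = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    sv = sv[:, ::stride, ::stride]                  # (C, oh, ow, k, k)
    col = sv.transpose(1, 2, 0, 3, 4).reshape(oh * ow, ci * k * k)
    out = col @ w.reshape(co, -1).T
    if bias is not None:
        out = out + bias
    return out.T.reshape(co, oh, ow)


def _bn(x: np.ndarray, p: Mapping[str, np.ndarray], prefix: str) -> np.ndarray:
    g, b = p[f"{prefix}gamma"], p[f"{prefix}beta"]
    m, v = p[f"{prefix}mean"], p[f"{prefix}var"]
    return (g / np.sqrt(v + 1e-5))[:, None, None] * (x - m[:, None, None]) \
        + b[:, None, None]


def _conv_bn_act(x, p, prefix, stride=1):
    return _hardswish(_bn(_conv2d(x, p[f"{prefix}w"], stride), p, f"{prefix}bn_"))


def _upsample2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=1).repeat(2, axis=2)


def _avgpool2(x: np.ndarray) -> np.ndarray:
    c, h, w = x.shape
    return x.reshape(c, h // 2, 2, w // 2, 2).mean(axis=(2, 4))


def _eval_csp_v1(x: np.ndarray, p: Mapping[str, np.ndarray], n: int) -> np.ndarray:
    y = _conv_bn_act(x, p, "cv1_")
    for i in range(n):
        z = _conv_bn_act(y, p, f"m{i}_a_")
        z = _conv_bn_act(z, p, f"m{i}_b_")
        y = y + z                                    # residual bottleneck
    short = _conv2d(x, p["cv2_w"])
    cat = np.concatenate([y, short], axis=0)
    cat = _hardswish(_bn(cat, p, "cat_bn_"))
    return _conv_bn_act(cat, p, "cv4_")


def _eval_se(x: np.ndarray, p: Mapping[str, np.ndarray]) -> np.ndarray:
    s = x.mean(axis=(1, 2))
    h = np.maximum(p["w1"] @ s + p["b1"], 0.0)
    g = _sigmoid(p["w2"] @ h + p["b2"])
    return x * g[:, None, None]


def _he(rng: np.random.Generator, *shape) -> np.ndarray:
    fan_in = int(np.prod(shape[1:])) or 1
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)


def _bn_init(c: int) -> dict[str, np.ndarray]:
    return {"gamma": np.ones(c), "beta": np.zeros(c),
            "mean": np.zeros(c), "var": np.ones(c)}


def init_weights(graph: ArchGraph, rng: np.random.Generator | int = 0
                 ) -> dict[int, dict[str, np.ndarray]]:
    """Random (He) initialization keyed by layer index.

    Batch-norm running statistics are initialized to the identity transform
    (mean 0, var 1); keys ending in ``_mean``/``_var`` are not trainable.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    weights: dict[int, dict[str, np.ndarray]] = {}
    for l in graph.layers:
        p: dict[str, np.ndarray] = {}
        if l.kind in ("conv", "focus"):
            p["w"] = _he(rng, l.out_channels, l.in_channels, l.kernel, l.kernel)
            p.update({f"bn_{k}": v for k, v in _bn_init(l.out_channels).items()})
        elif l.kind == "bottleneck_csp_v1":
            c1, c2, c_ = l.in_channels, l.out_channels, l.out_channels // 2
            p["cv1_w"] = _he(rng, c_, c1, 1, 1)
            p.update({f"cv1_bn_{k}": v for k, v in _bn_init(c_).items()})
            for i in range(l.repeats):
                p[f"m{i}_a_w"] = _he(rng, c_, c_, 1, 1)
                p.update({f"m{i}_a_bn_{k}": v for k, v in _bn_init(c_).items()})
                p[f"m{i}_b_w"] = _he(rng, c_, c_, 3, 3)
                p.update({f"m{i}_b_bn_{k}": v for k, v in _bn_init(c_).items()})
            p["cv2_w"] = _he(rng, c_, c1, 1, 1)
            p.update({f"cat_bn_{k}": v for k, v in _bn_init(2 * c_).items()})
            p["cv4_w"] = _he(rng, c2, 2 * c_, 1, 1)
            p.update({f"cv4_bn_{k}": v for k, v in _bn_init(c2).items()})
        elif l.kind == "se_block":
            c, h = l.in_channels, l.in_channels // l.reduction
            p["w1"], p["b1"] = _he(rng, h, c), np.zeros(h)
            p["w2"], p["b2"] = _he(rng, c, h), np.zeros(c)
        elif l.kind == "batch_norm":
            p.update({f"bn_{k}": v for k, v in _bn_init(l.out_channels).items()})
        elif l.kind == "detect_head":
            p["w"] = _he(rng, l.out_channels, l.in_channels, 1, 1)
            p["b"] = np.zeros(l.out_channels)
        weights[l.index] = p
    return weights


def _check_weights(graph: ArchGraph, weights: Mapping[int, Mapping[str, np.ndarray]]) -> None:
    ref = init_weights(graph, 0)
    for idx, p_ref in ref.items():
        if not p_ref:
            continue
        if idx not in weights:
            raise ValueError(f"missing weights for layer {idx}")
        for key, arr in p_ref.items():
            got = weights[idx].get(key)
            if got is None or np.shape(got) != arr.shape:
                raise ValueError(
                    f"layer {idx}: weight {key!r} has shape "
                    f"{None if got is None else np.shape(got)}, expected {arr.shape}")


def forward(graph: ArchGraph, weights: Mapping[int, Mapping[str, np.ndarray]],
            image: np.ndarray) -> dict[int, np.ndarray]:
    """Evaluate the graph on one image (H, W, 3); returns per-layer outputs.

    Detect-head outputs are raw (no, H, W) maps in (C, H, W) layout.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[0] % 32 or img.shape[1] % 32:
        raise ValueError("image dimensions must be multiples of 32")
    outs: dict[int, np.ndarray] = {}
    for l in graph.layers:
        p = weights.get(l.index, {})
        if l.kind == "focus":
            x = focus_transform(img).transpose(2, 0, 1)
            outs[l.index] = _hardswish(_bn(_conv2d(x, p["w"]), p, "bn_"))
        elif l.kind == "conv":
            outs[l.index] = _conv_bn_act(outs[l.inputs[0]], p, "", stride=l.stride)
        elif l.kind == "bottleneck_csp_v1":
            outs[l.index] = _eval_csp_v1(outs[l.inputs[0]], p, l.repeats)
        elif l.kind == "se_block":
            outs[l.index] = _eval_se(outs[l.inputs[0]], p)
        elif l.kind == "upsample":
            outs[l.index] = _upsample2(outs[l.inputs[0]])
        elif l.kind == "concat":
            rescale = l.rescale or (1,) * len(l.inputs)
            parts = []
            for s, r in zip(l.inputs, rescale):
                t = outs[s]
                if r == 2:
                    t = _upsample2(t)
                elif r == -2:
                    t = _avgpool2(t)
                parts.append(t)
            outs[l.index] = np.concatenate(parts, axis=0)
        elif l.kind == "batch_norm":
            outs[l.index] = _bn(outs[l.inputs[0]], p, "bn_")
        elif l.kind == "activation":
            outs[l.index] = _hardswish(outs[l.inputs[0]])
        elif l.kind == "detect_head":
            outs[l.index] = _conv2d(outs[l.inputs[0]], p["w"], bias=p["b"])
    return outs


def nms(boxes: Sequence[BoundingBox], iou_threshold: float = DEFAULT_NMS_IOU
        ) -> list[BoundingBox]:
    """Greedy non-maximum suppression by descending confidence."""
    order = sorted(range(len(boxes)), key=lambda i: -boxes[i].conf)
    if not order:
        return []
    m = iou_matrix(boxes, boxes)
    keep: list[int] = []
    for i in order:
        if all(m[i, j] <= iou_threshold for j in keep):
            keep.append(i)
    return [boxes[i] for i in sorted(keep)]


def predict(graph: ArchGraph,
            weights: Mapping[int, Mapping[str, np.ndarray]],
            image: np.ndarray,
            conf_threshold: float = DEFAULT_CONF_THRESHOLD,
            nms_iou: float = DEFAULT_NMS_IOU) -> list[BoundingBox]:
    """Run the detector and decode boxes above ``conf_threshold``.

    Decoding follows the standard YOLO form (sigmoid centre offset within the
    cell, exponential size factor on the anchor prior); surviving boxes are
    clipped to the canvas and filtered by greedy NMS.
    """
    _check_weights(graph, weights)
    outs = forward(graph, weights, image)
    h_img, w_img = np.asarray(image).shape[:2]
    nc = graph.num_classes
    cand: list[BoundingBox] = []
    scale_names = ("small", "medium", "large")
    for head in graph.heads:
        stride = head.head_stride
        anchors = graph.anchor_config[stride]
        raw = outs[head.index]                       # (3*(5+nc), gh, gw)
        gh, gw = raw.shape[1:]
        raw = raw.reshape(3, 5 + nc, gh, gw)
        for a, (pw, ph) in enumerate(anchors):
            tx, ty, tw, th = raw[a, 0], raw[a, 1], raw[a, 2], raw[a, 3]
            conf = _sigmoid(raw[a, 4]) * _sigmoid(raw[a, 5:]).max(axis=0)
            ys, xs = np.nonzero(conf >= conf_threshold)
            for cy, cx in zip(ys, xs):
                bu = (float(_sigmoid(tx[cy, cx])) + cx) * stride
                bv = (float(_sigmoid(ty[cy, cx])) + cy) * stride
                bw = pw * math.exp(min(tw[cy, cx], 20.0))
                bh = ph * math.exp(min(th[cy, cx], 20.0))
                left = max(0.0, bu - bw / 2)
                top = max(0.0, bv - bh / 2)
                right = min(float(w_img), bu + bw / 2)
                bottom = min(float(h_img), bv + bh / 2)
                if right - left <= 0 or bottom - top <= 0:
                    continue
                cand.append(BoundingBox.from_corners(
                    left, top, right, bottom, conf=float(conf[cy, cx]),
                    scale_class=scale_names[a]))
    return nms(cand, nms_iou)


# --------------------------------------------------------------------------
# reporting

def summary(graph: ArchGraph) -> str:
    """Layer-by-layer text table with parameter counts and the total."""
    rows = [f"{'idx':>3}  {'kind':<20} {'in':>5} {'out':>5} {'k':>2} {'s':>2} "
            f"{'inputs':<12} {'params':>10}"]
    total = 0
    for l in graph.layers:
        p = layer_parameters(l)
        total += p
        rows.append(f"{l.index:>3}  {l.kind:<20} {l.in_channels:>5} "
                    f"{l.out_channels:>5} {l.kernel:>2} {l.stride:>2} "
                    f"{str(list(l.inputs)):<12} {p:>10,}")
    rows.append(f"{'':>54} total {total:>10,}")
    return "\n".join(rows)


def graph_to_json(graph: ArchGraph) -> str:
    """Machine-readable export of the graph."""
    payload = {
        "input_size": graph.input_size,
        "num_classes": graph.num_classes,
        "merges": [list(m) for m in graph.merges],
        "anchors": {str(k): [list(a) for a in v]
                    for k, v in graph.anchor_config.items()},
        "total_parameters": count_parameters(graph),
        "layers": [
            {"index": l.index, "kind": l.kind, "in_channels": l.in_channels,
             "out_channels": l.out_channels, "kernel": l.kernel,
             "stride": l.stride, "inputs": list(l.inputs),
             "repeats": l.repeats, "parameters": layer_parameters(l),
             "note": l.note}
            for l in graph.layers
        ],
    }
    return json.dumps(payload, indent=2)
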