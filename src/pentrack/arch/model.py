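"""Untrained detector graphs with exact parameter and FLOP accounting.

Builds the standard one-stage detector family (CSP backbone, PAN neck,
decoupled anchor-free head) in its n/s/m width/depth variants, optionally
with a grouped multi-scale attention block inserted at the backbone top
(after the pyramid-pooling layer), which is where attention comparisons in
this problem domain place it.

Two parameter totals are exposed: the raw sum over all weights, and the
"fused" total obtained after merging each batch norm into its convolution.
Published per-variant tables in this domain customarily print the fused
total, so ``ArchSummary.params_millions`` follows that convention; the raw
total is available as ``total_params``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .layers import (
    C2f,
    Concat,
    ConfigError,
    ConvBN,
    Detect,
    EMA,
    Module,
    Shape,
    SPPF,
    Upsample,
)

__all__ = [
    "ArchConfig",
    "ArchSummary",
    "LayerSummary",
    "DetectionModel",
    "VARIANTS",
    "build_ema_block",
    "build_detector",
    "summarize",
]

#: depth multiple, width multiple, max channels per published variant
VARIANTS: dict[str, tuple[float, float, int]] = {
    "n": (0.33, 0.25, 1024),
    "s": (0.33, 0.50, 1024),
    "m": (0.67, 0.75, 768),
}


@dataclass(frozen=True)
class ArchConfig:
    """Detector variant selection; two classes by default (pig, pig_fighting)."""

    variant: str = "n"
    num_classes: int = 2
    attention: str = "none"
    input_size: int = 640
    ema_groups: int = 8

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigError(f"unknown variant {self.variant!r}; expected one of {sorted(VARIANTS)}")
        if self.attention not in ("none", "ema"):
            raise ConfigError(f"unknown attention {self.attention!r}; expected 'none' or 'ema'")
        if self.num_classes < 1:
            raise ConfigError("num_classes must be >= 1")
        if self.input_size % 32 != 0 or self.input_size <= 0:
            raise ConfigError("input_size must be a positive multiple of 32")


def _make_divisible(x: float, divisor: int = 8) -> int:
    return int(math.ceil(x / divisor) * divisor)


@dataclass
class _Node:
    module: Module
    sources: list[int]  # indices of producing nodes; -1 is the model input
    name: str


class DetectionModel:
    """Ordered layer graph; forward on (3, H, W) yields three head maps."""

    def __init__(self, nodes: list[_Node], config: ArchConfig) -> None:
        self.nodes = nodes
        self.config = config

    def forward(self, x: np.ndarray) -> list[np.ndarray]:
        outputs: list[np.ndarray | list[np.ndarray]] = []
        for node in self.nodes:
            ins = [x if j == -1 else outputs[j] for j in node.sources]
            outputs.append(node.module.forward(ins if len(ins) > 1 else ins[0]))
        return outputs[-1]

    def profile(self, input_size: int | None = None) -> tuple[int, list]:
        """Total MACs and per-node output shapes at ``input_size``."""
        size = input_size or self.config.input_size
        shapes: list = []
        total = 0
        inp: Shape = (3, size, size)
        for node in self.nodes:
            ins = [inp if j == -1 else shapes[j] for j in node.sources]
            macs, out = node.module.profile(ins if len(ins) > 1 else ins[0])
            total += macs
            shapes.append(out)
        return total, shapes

    def param_count(self) -> int:
        return sum(n.module.param_count() for n in self.nodes)

    def fused_param_count(self) -> int:
        return sum(n.module.fused_param_count() for n in self.nodes)


def build_ema_block(channels: int, groups: int = 8) -> EMA:
    """Standalone grouped multi-scale attention block."""
    return EMA(channels, groups, rng=np.random.default_rng(0))


def build_detector(config: ArchConfig) -> DetectionModel:
    """Construct the layer graph for a variant (untrained, deterministic)."""
    depth, width, max_ch = VARIANTS[config.variant]
    rng = np.random.default_rng(0)

    def cw(c: int) -> int:
        return _make_divisible(min(c, max_ch) * width)

    def dn(n: int) -> int:
        return max(round(n * depth), 1)

    nodes: list[_Node] = []

    def add(module: Module, sources: list[int], name: str) -> int:
        nodes.append(_Node(module, sources, name))
        return len(nodes) - 1

    # backbone
    i = add(ConvBN(3, cw(64), 3, 2, rng=rng), [-1], "stem")
    i = add(ConvBN(cw(64), cw(128), 3, 2, rng=rng), [i], "down2")
    i = add(C2f(cw(128), cw(128), dn(3), True, rng), [i], "stage2")
    i = add(ConvBN(cw(128), cw(256), 3, 2, rng=rng), [i], "down3")
    p3 = add(C2f(cw(256), cw(256), dn(6), True, rng), [i], "stage3")
    i = add(ConvBN(cw(256), cw(512), 3, 2, rng=rng), [p3], "down4")
    p4 = add(C2f(cw(512), cw(512), dn(6), True, rng), [i], "stage4")
    i = add(ConvBN(cw(512), cw(1024), 3, 2, rng=rng), [p4], "down5")
    i = add(C2f(cw(1024), cw(1024), dn(3), True, rng), [i], "stage5")
    top = add(SPPF(cw(1024), cw(1024), 5, rng), [i], "sppf")
    if config.attention == "ema":
        top = add(EMA(cw(1024), config.ema_groups, rng=rng), [top], "ema")

    # neck (path aggregation)
    i = add(Upsample(), [top], "up1")
    i = add(Concat(), [i, p4], "cat1")
    n4 = add(C2f(cw(512) + cw(1024), cw(512), dn(3), False, rng), [i], "neck4")
    i = add(Upsample(), [n4], "up2")
    i = add(Concat(), [i, p3], "cat2")
    n3 = add(C2f(cw(256) + cw(512), cw(256), dn(3), False, rng), [i], "neck3")
    i = add(ConvBN(cw(256), cw(256), 3, 2, rng=rng), [n3], "pan_down1")
    i = add(Concat(), [i, n4], "cat3")
    o4 = add(C2f(cw(256) + cw(512), cw(512), dn(3), False, rng), [i], "out4")
    i = add(ConvBN(cw(512), cw(512), 3, 2, rng=rng), [o4], "pan_down2")
    i = add(Concat(), [i, top], "cat4")
    o5 = add(C2f(cw(512) + cw(1024), cw(1024), dn(3), False, rng), [i], "out5")

    head_ch = (cw(256), cw(512), cw(1024))
    add(Detect(config.num_classes, head_ch, rng), [n3, o4, o5], "detect")
    return DetectionModel(nodes, config)


@dataclass
class LayerSummary:
    index: int
    name: str
    params: int
    out_shape: tuple


@dataclass
class ArchSummary:
    """Parameter and FLOP totals of a constructed (untrained) variant."""

    variant: str
    num_classes: int
    attention: str
    input_size: int
    total_params: int
    fused_params: int
    flops_raw: int
    layers: list[LayerSummary] = field(default_factory=list)

    @property
    def params_millions(self) -> float:
        """Fused-total millions, 2 decimals (the published-table convention)."""
        return round(self.fused_params / 1e6, 2)

    @property
    def raw_params_millions(self) -> float:
        return round(self.total_params / 1e6, 2)

    @property
    def flops_g(self) -> float:
        """Billions of floating-point ops, MAC counted as 2, 1 decimal."""
        return round(self.flops_raw / 1e9, 1)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "num_classes": self.num_classes,
            "attention": self.attention,
            "input_size": self.input_size,
            "total_params": self.total_params,
            "fused_params": self.fused_params,
            "params_millions": self.params_millions,
            "flops_g": self.flops_g,
            "layers": [
                {
                    "index": l.index,
                    "name": l.name,
                    "params": l.params,
                    "out_shape": list(l.out_shape),
                }
                for l in self.layers
            ],
        }


def summarize(model: DetectionModel, input_size: int | None = None) -> ArchSummary:
    """Exact parameter totals and 2xMAC FLOPs of a built graph."""
    size = input_size or model.config.input_size
    macs, shapes = model.profile(size)
    layers = [
        LayerSummary(
            idx,
            node.name,
            node.module.param_count(),
            tuple(shapes[idx]) if not isinstance(shapes[idx], list) else tuple(map(tuple, shapes[idx])),
        )
        for idx, node in enumerate(model.nodes)
    ]
    total = model.param_count()
    assert total == sum(l.params for l in layers)
    return ArchSummary(
        variant=model.config.variant,
        num_classes=model.config.num_classes,
        attention=model.config.attention,
        input_size=size,
        total_params=total,
        fused_params=model.fused_param_count(),
        flops_raw=2 * macs,
        layers=layers,
    )
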