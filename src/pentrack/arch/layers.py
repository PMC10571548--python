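"""Minimal numpy layer toolkit for structural verification of detectors.

Each module carries real (randomly initialized) weights so a forward pass
can be executed, plus analytic accounting: exact parameter totals and
multiply-accumulate counts at a given input size.  Reported FLOPs follow
the detector family's customary convention — convolution MACs only, each
counted as two floating-point operations.

Activations are single-image ``(C, H, W)`` float32 arrays; there is no
autograd, no training, and no weight loading.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ConfigError",
    "Module",
    "ConvBN",
    "RawConv",
    "Bottleneck",
    "C2f",
    "SPPF",
    "Upsample",
    "Concat",
    "EMA",
    "Detect",
]

Shape = tuple[int, int, int]


class ConfigError(ValueError):
    """Invalid architecture configuration."""


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def _silu(x: np.ndarray) -> np.ndarray:
    return x * _sigmoid(x)


def _softmax(x: np.ndarray, axis: int) -> np.ndarray:
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray | None, stride: int, pad: int) -> np.ndarray:
    """Direct im2col convolution on a (C, H, W) input."""
    co, ci, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    _, hp, wp = xp.shape
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    s0, s1, s2 = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp,
        shape=(ci, ho, wo, kh, kw),
        strides=(s0, s1 * stride, s2 * stride, s1, s2),
        writeable=False,
    )
    col = view.transpose(1, 2, 0, 3, 4).reshape(ho * wo, ci * kh * kw)
    out = col @ w.reshape(co, ci * kh * kw).T
    if b is not None:
        out += b
    return np.ascontiguousarray(out.T.reshape(co, ho, wo))


def _conv_out_hw(h: int, w: int, k: int, stride: int, pad: int) -> tuple[int, int]:
    return (h + 2 * pad - k) // stride + 1, (w + 2 * pad - k) // stride + 1


class Module:
    """Base: children-recursive parameters, forward, and MAC profiling."""

    def __init__(self) -> None:
        self._children: list[tuple[str, "Module"]] = []
        self._params: list[tuple[str, np.ndarray, bool]] = []

    def add_child(self, name: str, child: "Module") -> "Module":
        self._children.append((name, child))
        return child

    def register(self, name: str, array: np.ndarray, trainable: bool = True) -> np.ndarray:
        self._params.append((name, array, trainable))
        return array

    def parameters(self, prefix: str = "") -> list[tuple[str, np.ndarray, bool]]:
        out = [(prefix + n, a, t) for n, a, t in self._params]
        for cname, child in self._children:
            out.extend(child.parameters(prefix + cname + "."))
        return out

    def param_count(self) -> int:
        """All parameters, trainable or frozen (the family's reported total)."""
        return sum(a.size for _, a, _ in self.parameters())

    def fused_param_count(self) -> int:
        """Parameter total after merging each BN into its convolution."""
        out = sum(a.size for _, a, _ in self._params)
        return out + sum(c.fused_param_count() for _, c in self._children)

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def profile(self, shape):  # pragma: no cover - abstract
        raise NotImplementedError


class ConvBN(Module):
    """k x k convolution + batch norm + SiLU (the family's standard block)."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.c1, self.c2, self.k, self.s = c1, c2, k, s
        self.p = k // 2
        scale = np.sqrt(2.0 / (c1 * k * k))
        self.w = self.register("weight", (rng.standard_normal((c2, c1, k, k)) * scale).astype(np.float32))
        self.bn_gamma = self.register("bn.weight", np.ones(c2, dtype=np.float32))
        self.bn_beta = self.register("bn.bias", np.zeros(c2, dtype=np.float32))
        # running stats: buffers, not parameters
        self._mu = np.zeros(c2, dtype=np.float32)
        self._var = np.ones(c2, dtype=np.float32)

    def fused_param_count(self) -> int:
        # BN folds into the conv: gamma/beta (2*c2) replaced by a bias (c2)
        return self.w.size + self.c2

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = conv2d(x, self.w, None, self.s, self.p)
        inv = self.bn_gamma / np.sqrt(self._var + 1e-3)
        y = y * inv[:, None, None] + (self.bn_beta - self._mu * inv)[:, None, None]
        return _silu(y)

    def profile(self, shape: Shape) -> tuple[int, Shape]:
        c, h, w = shape
        if c != self.c1:
            raise ConfigError(f"expected {self.c1} channels, got {c}")
        ho, wo = _conv_out_hw(h, w, self.k, self.s, self.p)
        return self.k * self.k * self.c1 * self.c2 * ho * wo, (self.c2, ho, wo)


class RawConv(Module):
    """Plain convolution with bias, no norm, no activation."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1, p: int | None = None,
                 trainable: bool = True, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.c1, self.c2, self.k, self.s = c1, c2, k, s
        self.p = k // 2 if p is None else p
        scale = np.sqrt(2.0 / (c1 * k * k))
        self.w = self.register("weight", (rng.standard_normal((c2, c1, k, k)) * scale).astype(np.float32), trainable)
        self.b = self.register("bias", np.zeros(c2, dtype=np.float32), trainable)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return conv2d(x, self.w, self.b, self.s, self.p)

    def profile(self, shape: Shape) -> tuple[int, Shape]:
        c, h, w = shape
        ho, wo = _conv_out_hw(h, w, self.k, self.s, self.p)
        return self.k * self.k * self.c1 * self.c2 * ho * wo, (self.c2, ho, wo)


class Bottleneck(Module):
    """Two 3x3 ConvBN blocks with an optional residual add."""

    def __init__(self, c: int, shortcut: bool, rng: np.random.Generator) -> None:
        super().__init__()
        self.shortcut = shortcut
        self.cv1 = self.add_child("cv1", ConvBN(c, c, 3, rng=rng))
        self.cv2 = self.add_child("cv2", ConvBN(c, c, 3, rng=rng))

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.cv2.forward(self.cv1.forward(x))
        return x + y if self.shortcut else y

    def profile(self, shape: Shape) -> tuple[int, Shape]:
        m1, s1 = self.cv1.profile(shape)
        m2, s2 = self.cv2.profile(s1)
        return m1 + m2, s2


class C2f(Module):
    """Split/transform/concat block with n bottlenecks (CSP-style)."""

    def __init__(self, c1: int, c2: int, n: int, shortcut: bool, rng: np.random.Generator) -> None:
        super().__init__()
        self.c = c2 // 2
        self.n = n
        self.cv1 = self.add_child("cv1", ConvBN(c1, 2 * self.c, 1, rng=rng))
        self.m = [
            self.add_child(f"m.{i}", Bottleneck(self.c, shortcut, rng))
            for i in range(n)
        ]
        self.cv2 = self.add_child("cv2", ConvBN((2 + n) * self.c, c2, 1, rng=rng))

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.cv1.forward(x)
        parts = [y[: self.c], y[self.c :]]
        for blk in self.m:
            parts.append(blk.forward(parts[-1]))
        return self.cv2.forward(np.concatenate(parts, axis=0))

    def profile(self, shape: Shape) -> tuple[int, Shape]:
        macs, s = self.cv1.profile(shape)
        part = (self.c, s[1], s[2])
        for blk in self.m:
            m, part = blk.profile(part)
            macs += m
        m, out = self.cv2.profile(((2 + self.n) * self.c, s[1], s[2]))
        return macs + m, out


class SPPF(Module):
    """Spatial pyramid pooling (fast): three chained 5x5 max pools."""

    def __init__(self, c1: int, c2: int, k: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.k = k
        c_ = c1 // 2
        self.cv1 = self.add_child("cv1", ConvBN(c1, c_, 1, rng=rng))
        self.cv2 = self.add_child("cv2", ConvBN(c_ * 4, c2, 1, rng=rng))

    def _pool(self, x: np.ndarray) -> np.ndarray:
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p)), constant_values=-np.inf)
        view = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(1, 2))
        return view.max(axis=(-1, -2))

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.cv1.forward(x)
        p1 = self._pool(y)
        p2 = self._pool(p1)
        p3 = self._pool(p2)
        return self.cv2.forward(np.concatenate([y, p1, p2, p3], axis=0))

    def profile(self, shape: Shape) -> tuple[int, Shape]:
        macs, s = self.cv1.profile(shape)
        m, out = self.cv2.profile((s[0] * 4, s[1], s[2]))
        return macs + m, out


class Upsample(Module):
    """Nearest-neighbour 2x upsample (no parameters)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def profile(self, shape: Shape) -> tuple[int, Shape]:
        c, h, w = shape
        return 0, (c, 2 * h, 2 * w)


class Concat(Module):
    """Channel concatenation of multiple inputs."""

    def forward(self, xs: list[np.ndarray]) -> np.ndarray:
        return np.concatenate(xs, axis=0)

    def profile(self, shapes: list[Shape]) -> tuple[int, Shape]:
        hws = {(h, w) for _, h, w in shapes}
        if len(hws) != 1:
            raise ConfigError(f"concat inputs disagree spatially: {shapes}")
        (h, w), = hws
        return 0, (sum(c for c, _, _ in shapes), h, w)


class EMA(Module):
    """Grouped multi-scale attention: directional pooling + 1x1 and 3x3
    branches, cross-branch softmax spatial weighting, sigmoid gating.

    Maps (C, H, W) to (C, H, W); parameters are independent of H and W.
    """

    def __init__(self, channels: int, groups: int = 8, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if channels % groups != 0:
            raise ConfigError(f"groups ({groups}) must divide channels ({channels})")
        rng = rng or np.random.default_rng(0)
        self.channels, self.groups = channels, groups
        cg = channels // groups
        self.cg = cg
        self.conv1x1 = self.add_child("conv1x1", RawConv(cg, cg, 1, rng=rng))
        self.conv3x3 = self.add_child("conv3x3", RawConv(cg, cg, 3, rng=rng))
        self.gn_gamma = self.register("gn.weight", np.ones(cg, dtype=np.float32))
        self.gn_beta = self.register("gn.bias", np.zeros(cg, dtype=np.float32))

    def _group_norm(self, x: np.ndarray) -> np.ndarray:
        # one group per channel: per-(group, channel) spatial normalization
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        y = (x - mu) / np.sqrt(var + 1e-5)
        return y * self.gn_gamma[None, :, None, None] + self.gn_beta[None, :, None, None]

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        if c != self.channels:
            raise ConfigError(f"expected {self.channels} channels, got {c}")
        g, cg = self.groups, self.cg
        gx = x.reshape(g, cg, h, w)
        x_h = gx.mean(axis=3, keepdims=True)                       # (g, cg, H, 1)
        x_w = gx.mean(axis=2, keepdims=True).transpose(0, 1, 3, 2)  # (g, cg, W, 1)
        strip = np.concatenate([x_h, x_w], axis=2)                  # (g, cg, H+W, 1)
        w11 = self.conv1x1.w[:, :, 0, 0]
        hw = np.einsum("oc,gcsl->gosl", w11, strip) + self.conv1x1.b[None, :, None, None]
        a_h, a_w = hw[:, :, :h], hw[:, :, h:]
        gate = _sigmoid(a_h) * _sigmoid(a_w.transpose(0, 1, 3, 2))
        x1 = self._group_norm(gx * gate)
        x2 = np.stack([self.conv3x3.forward(gx[i]) for i in range(g)])
        x11 = _softmax(x1.mean(axis=(2, 3)), axis=1)[:, None, :]    # (g, 1, cg)
        x21 = _softmax(x2.mean(axis=(2, 3)), axis=1)[:, None, :]
        x12 = x2.reshape(g, cg, h * w)
        x22 = x1.reshape(g, cg, h * w)
        weights = (x11 @ x12 + x21 @ x22).reshape(g, 1, h, w)
        return (gx * _sigmoid(weights)).reshape(c, h, w)

    def profile(self, shape: Shape) -> tuple[int, Shape]:
        c, h, w = shape
        g, cg = self.groups, self.cg
        macs = g * cg * cg * (h + w)        # 1x1 branch on pooled strips
        macs += g * 9 * cg * cg * h * w     # 3x3 branch
        macs += 2 * g * cg * h * w          # two cross-branch matmuls
        return macs, shape


class Detect(Module):
    """Anchor-free decoupled head over three feature scales.

    Per scale a regression branch emits ``4 * reg_max`` distribution bins
    and a classification branch emits ``nc`` logits; the distribution-focal
    projection is a frozen 16-tap convolution (counted in parameter totals,
    as the family reports it).
    """

    REG_MAX = 16

    def __init__(self, nc: int, ch: tuple[int, ...], rng: np.random.Generator) -> None:
        super().__init__()
        if nc < 1:
            raise ConfigError(f"num_classes must be >= 1, got {nc}")
        self.nc = nc
        self.ch = tuple(ch)
        c2 = max(16, ch[0] // 4, self.REG_MAX * 4)
        c3 = max(ch[0], min(nc, 100))
        self.cv2 = []
        self.cv3 = []
        for i, x in enumerate(ch):
            self.cv2.append(
                (
                    self.add_child(f"cv2.{i}.0", ConvBN(x, c2, 3, rng=rng)),
                    self.add_child(f"cv2.{i}.1", ConvBN(c2, c2, 3, rng=rng)),
                    self.add_child(f"cv2.{i}.2", RawConv(c2, 4 * self.REG_MAX, 1, rng=rng)),
                )
            )
            self.cv3.append(
                (
                    self.add_child(f"cv3.{i}.0", ConvBN(x, c3, 3, rng=rng)),
                    self.add_child(f"cv3.{i}.1", ConvBN(c3, c3, 3, rng=rng)),
                    self.add_child(f"cv3.{i}.2", RawConv(c3, nc, 1, rng=rng)),
                )
            )
        dfl = np.arange(self.REG_MAX, dtype=np.float32).reshape(1, self.REG_MAX, 1, 1)
        self.dfl_w = self.register("dfl.conv.weight", dfl, trainable=False)

    def forward(self, xs: list[np.ndarray]) -> list[np.ndarray]:
        outs = []
        for x, cv2, cv3 in zip(xs, self.cv2, self.cv3):
            box = cv2[2].forward(cv2[1].forward(cv2[0].forward(x)))
            cls = cv3[2].forward(cv3[1].forward(cv3[0].forward(x)))
            outs.append(np.concatenate([box, cls], axis=0))
        return outs

    def profile(self, shapes: list[Shape]) -> tuple[int, list[Shape]]:
        macs = 0
        outs = []
        for shape, cv2, cv3 in zip(shapes, self.cv2, self.cv3):
            s = shape
            for blk in cv2:
                m, s = blk.profile(s)
                macs += m
            s2 = shape
            for blk in cv3:
                m, s2 = blk.profile(s2)
                macs += m
            outs.append((s[0] + s2[0], s[1], s[2]))
            # frozen distribution-focal projection: 16 taps x 4 sides x anchors
            macs += self.REG_MAX * 4 * shape[1] * shape[2]
        return macs, outs
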