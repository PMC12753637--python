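"""U-Net style encoder-decoder built from residual blocks.

Two architectures are provided:

``full``
    ResNet-34-pattern encoder: 7x7 stem convolution producing 64 feature
    maps at stride 2, 2x2 max-pool, residual stages (64x3, 128x4, 256x6,
    512x3) and a 3x3 widening convolution to a 1024-channel bottleneck at
    1/32 of the input resolution. The decoder upsamples with 2x2 transpose
    convolutions, concatenating the skip feature map of matching resolution
    after each upsampling step.

``reduced``
    Same topology at desk scale: 3x3 stem to 16 maps at stride 1, one
    residual block per stage (32, 64), 128-channel bottleneck at 1/8
    resolution. Intended for CPU training on small synthetic patches.

Inputs must have spatial dimensions divisible by 32 (both variants share the
contract so patch-size handling is uniform); violations raise
:class:`ShapeError`.
"""

from __future__ import annotations

import numpy as np

from .layers import Conv2d, ConvTranspose2d, GroupNorm, MaxPool2d, ReLU, Param

__all__ = ["UNet", "ShapeError", "ARCHITECTURES"]

DIVISIBILITY = 32

ARCHITECTURES = {
    # stem: (kernel, stride, channels, pool_after)
    # stages: list of (channels, n_blocks, first_stride)
    "full": {
        "stem": (7, 2, 64, True),
        "stages": [(64, 3, 1), (128, 4, 2), (256, 6, 2), (512, 3, 2)],
        "bottleneck": 1024,
    },
    "reduced": {
        "stem": (3, 1, 16, False),
        "stages": [(32, 1, 2), (64, 1, 2), (128, 1, 2)],
        "bottleneck": None,  # last stage already is the bottleneck
    },
}


class ShapeError(ValueError):
    """Input spatial shape not accepted by the model."""


class ResidualBlock:
    """conv-norm-ReLU-conv-norm added to a (possibly projected) shortcut."""

    def __init__(self, c_in: int, c_out: int, stride: int, rng):
        self.conv1 = Conv2d(c_in, c_out, 3, stride=stride, rng=rng)
        self.gn1 = GroupNorm(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, rng=rng)
        self.gn2 = GroupNorm(c_out)
        self.proj = (Conv2d(c_in, c_out, 1, stride=stride, pad=0, rng=rng)
                     if (stride != 1 or c_in != c_out) else None)
        self.relu2 = ReLU()

    def params(self):
        ps = (self.conv1.params() + self.gn1.params() + self.conv2.params()
              + self.gn2.params())
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def forward(self, x):
        h = self.relu1.forward(self.gn1.forward(self.conv1.forward(x)))
        h = self.gn2.forward(self.conv2.forward(h))
        s = self.proj.forward(x) if self.proj is not None else x
        return self.relu2.forward(h + s)

    def backward(self, dy):
        d = self.relu2.backward(dy)
        dh = self.conv1.backward(self.gn1.backward(self.relu1.backward(
            self.conv2.backward(self.gn2.backward(d)))))
        if self.proj is not None:
            dh = dh + self.proj.backward(d)
        else:
            dh = dh + d
        return dh


class _DecoderStep:
    """Transpose-conv upsampling, optional skip concatenation, 3x3 conv."""

    def __init__(self, c_in: int, c_skip: int, c_out: int, rng):
        self.up = ConvTranspose2d(c_in, c_out, 2, rng=rng)
        self.gn_up = GroupNorm(c_out)
        self.c_skip = c_skip
        self.conv = Conv2d(c_out + c_skip, c_out, 3, rng=rng)
        self.gn = GroupNorm(c_out)
        self.relu_up = ReLU()
        self.relu = ReLU()

    def params(self):
        return (self.up.params() + self.gn_up.params() + self.conv.params()
                + self.gn.params())

    def forward(self, x, skip):
        u = self.relu_up.forward(self.gn_up.forward(self.up.forward(x)))
        if skip is not None:
            u = np.concatenate([u, skip], axis=1)
        self._c_up = u.shape[1] - (skip.shape[1] if skip is not None else 0)
        return self.relu.forward(self.gn.forward(self.conv.forward(u)))

    def backward(self, dy):
        du = self.conv.backward(self.gn.backward(self.relu.backward(dy)))
        if self.c_skip:
            du, dskip = du[:, :self._c_up], du[:, self._c_up:]
        else:
            dskip = None
        dx = self.up.backward(self.gn_up.backward(self.relu_up.backward(
            np.ascontiguousarray(du))))
        return dx, dskip


class UNet:
    """Three-class semantic segmentation network (background/positive/negative)."""

    N_CLASSES = 3

    def __init__(self, variant: str = "full", seed: int = 0):
        if variant not in ARCHITECTURES:
            raise ValueError(f"unknown architecture variant: {variant!r}")
        self.variant = variant
        self.seed = int(seed)
        arch = ARCHITECTURES[variant]
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA5]))

        k, s, c0, pool = arch["stem"]
        self.stem = Conv2d(3, c0, k, stride=s, rng=rng)
        self.stem_gn = GroupNorm(c0)
        self.stem_relu = ReLU()
        self.pool = MaxPool2d() if pool else None

        # skip feature maps: stem output, then every stage output except the last
        self.stages: list[list[ResidualBlock]] = []
        c_prev = c0
        skip_channels = [c0]
        for c, n_blocks, stride in arch["stages"]:
            blocks = [ResidualBlock(c_prev, c, stride, rng)]
            blocks += [ResidualBlock(c, c, 1, rng) for _ in range(n_blocks - 1)]
            self.stages.append(blocks)
            skip_channels.append(c)
            c_prev = c
        skip_channels.pop()  # the last stage feeds the bottleneck, not a skip

        if arch["bottleneck"]:
            self.widen = Conv2d(c_prev, arch["bottleneck"], 3, rng=rng)
            self.widen_gn = GroupNorm(arch["bottleneck"])
            self.widen_relu = ReLU()
            c_prev = arch["bottleneck"]
        else:
            self.widen = None

        # total downsampling factor determines the number of upsampling steps
        factor = s * (2 if pool else 1)
        for _, _, stride in arch["stages"]:
            factor *= stride
        self.factor = factor
        n_ups = int(np.log2(factor))

        self.decoder: list[_DecoderStep] = []
        skips = list(reversed(skip_channels))  # deepest skip first
        for i in range(n_ups):
            c_skip = skips[i] if i < len(skips) else 0
            c_out = max(c_skip, 16) if c_skip else max(c_prev // 2, 16)
            self.decoder.append(_DecoderStep(c_prev, c_skip, c_out, rng))
            c_prev = c_out
        self.head = Conv2d(c_prev, self.N_CLASSES, 1, pad=0, rng=rng)

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> list[Param]:
        ps = self.stem.params() + self.stem_gn.params()
        for stage in self.stages:
            for b in stage:
                ps += b.params()
        if self.widen is not None:
            ps += self.widen.params() + self.widen_gn.params()
        for step in self.decoder:
            ps += step.params()
        ps += self.head.params()
        return ps

    def state_arrays(self) -> list[np.ndarray]:
        return [p.value for p in self.params()]

    def load_state_arrays(self, arrays) -> None:
        params = self.params()
        if len(arrays) != len(params):
            raise ValueError("checkpoint parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.value.shape != a.shape:
                raise ValueError("checkpoint parameter shape mismatch")
            p.value[...] = a

    # -- forward / backward -------------------------------------------------
    def check_shape(self, h: int, w: int) -> None:
        if h % DIVISIBILITY or w % DIVISIBILITY:
            raise ShapeError(
                f"input spatial shape {h}x{w} must be divisible by {DIVISIBILITY}")

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Map a (N,3,H,W) float batch to (N,3,H,W) class logits."""
        self.check_shape(x.shape[2], x.shape[3])
        h = self.stem_relu.forward(self.stem_gn.forward(self.stem.forward(x)))
        skips = [h]
        if self.pool is not None:
            h = self.pool.forward(h)
        for stage in self.stages[:-1]:
            for block in stage:
                h = block.forward(h)
            skips.append(h)
        for block in self.stages[-1]:
            h = block.forward(h)
        if self.widen is not None:
            h = self.widen_relu.forward(self.widen_gn.forward(
                self.widen.forward(h)))
        self._n_skips = len(skips)
        skips.reverse()
        for i, step in enumerate(self.decoder):
            h = step.forward(h, skips[i] if i < len(skips) else None)
        return self.head.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips = []
        for step in reversed(self.decoder):
            d, dskip = step.backward(d)
            dskips.append(dskip)
        # reorder so pop(0) yields the deepest consumed skip first
        dskips = dskips[::-1][:self._n_skips]
        if self.widen is not None:
            d = self.widen.backward(self.widen_gn.backward(
                self.widen_relu.backward(d)))
        for block in reversed(self.stages[-1]):
            d = block.backward(d)
        for stage_i in range(len(self.stages) - 2, -1, -1):
            d = d + dskips.pop(0)
            for block in reversed(self.stages[stage_i]):
                d = block.backward(d)
        if self.pool is not None:
            d = self.pool.backward(d)
        d = d + dskips.pop(0)
        self.stem.backward(self.stem_gn.backward(self.stem_relu.backward(d)))
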