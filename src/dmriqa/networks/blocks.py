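"""Residual block variants composing the assessment networks."""

from __future__ import annotations

import numpy as np

from .layers import (
    BatchNorm,
    Conv3x3,
    DepthwiseConv3x3,
    GlobalAvgPool,
    Layer,
    MaxPool2x2,
    NonlocalBlock,
    PointwiseConv,
    ReLU,
    softmax,
)

__all__ = [
    "DSConvUnit",
    "DSRBlock",
    "NLDRBlock",
    "NLRBlock",
    "CLFBlock",
    "dsconv_param_count",
]


def dsconv_param_count(c_in: int, c_out: int, bias: bool = False) -> int:
    """Closed-form parameter count of one depthwise separable convolution:
    9*c_in depthwise weights + c_in*c_out pointwise weights (+ c_out bias)."""
    return 9 * c_in + c_in * c_out + (c_out if bias else 0)


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        super().__init__()
        self.children = list(layers)

    def forward(self, x, training=False):
        for layer in self.children:
            x = layer.forward(x, training)
        return x

    def backward(self, dy):
        for layer in reversed(self.children):
            dy = layer.backward(dy)
        return dy


class DSConvUnit(Sequential):
    """Depthwise separable conv -> BN -> ReLU (no conv bias; BN follows)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__(
            DepthwiseConv3x3(c_in, rng=rng),
            PointwiseConv(c_in, c_out, rng=rng),
            BatchNorm(c_out),
            ReLU(),
        )


class _ResidualDown(Layer):
    """Shared skeleton of DSR/NLDR: main path + strided 1x1 shortcut, summed.

    Main path: two DSConv units (optionally a nonlocal residual insert)
    then 2x2 max-pooling; shortcut: 1x1 convolution with stride 2.  Halves
    both spatial dimensions; requires them even.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 nonlocal_insert: bool) -> None:
        super().__init__()
        main: list[Layer] = [DSConvUnit(c_in, c_out, rng), DSConvUnit(c_out, c_out, rng)]
        if nonlocal_insert:
            main.append(NLRBlock(c_out, rng))
        main.append(MaxPool2x2())
        self.main = Sequential(*main)
        self.shortcut = PointwiseConv(c_in, c_out, stride=2, rng=rng)
        self.children = [self.main, self.shortcut]

    def forward(self, x, training=False):
        if x.shape[1] % 2 or x.shape[2] % 2:
            raise ValueError(f"residual down-block needs even spatial dims, got {x.shape[1:3]}")
        return self.main.forward(x, training) + self.shortcut.forward(x, training)

    def backward(self, dy):
        return self.main.backward(dy) + self.shortcut.backward(dy)


class DSRBlock(_ResidualDown):
    """Depthwise separable residual block (2x spatial down-sampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__(c_in, c_out, rng, nonlocal_insert=False)


class NLDRBlock(_ResidualDown):
    """DSR block with a nonlocal residual insert before max-pooling."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__(c_in, c_out, rng, nonlocal_insert=True)


class NLRBlock(Layer):
    """Nonlocal residual block: x + nonlocal(x); shape preserved."""

    def __init__(self, c: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.nonlocal_op = NonlocalBlock(c, rng=rng)
        self.children = [self.nonlocal_op]

    def forward(self, x, training=False):
        return x + self.nonlocal_op.forward(x, training)

    def backward(self, dy):
        return dy + self.nonlocal_op.backward(dy)


class CLFBlock(Layer):
    """Classifier head: 3x3 conv to 3 channels, GAP, softmax.

    ``forward`` returns probabilities; the pre-softmax logits of the last
    call are kept so a loss can inject its gradient via
    ``backward_from_logits``.
    """

    def __init__(self, c_in: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.conv = Conv3x3(c_in, 3, bias=True, rng=rng)
        self.gap = GlobalAvgPool()
        self.children = [self.conv, self.gap]

    def forward(self, x, training=False):
        z = self.conv.forward(x, training)
        self.logits = self.gap.forward(z, training)
        return softmax(self.logits, axis=-1)

    def backward_from_logits(self, dlogits):
        return self.conv.backward(self.gap.backward(dlogits))

    def backward(self, dy):  # pragma: no cover - training always uses logits
        raise NotImplementedError("backpropagate through the loss via backward_from_logits")
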