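"""Architecture builders for the two-stage cascade.

The primary network is a U-Net-style encoder-decoder that maps a single-channel
T2 FLAIR slice to per-pixel class probabilities (2 classes for plain lesion
segmentation, 3 when background/FCI/LACI are segmented jointly). The secondary
network is a small CNN classifier that maps a 64x64 T1 ROI patch to a single
probability that the lesion is a lacunar infarct (LACI).

Both builders return network objects with ``forward_logits`` / ``backward``
(training) and ``predict_proba`` (evaluation) methods plus ``params()`` for the
optimizer, ``state_dict()`` / ``load_state_dict()`` for serialization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import (
    AvgPool2d,
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Dropout,
    Flatten,
    GlobalAvgPool2d,
    Linear,
    MaxPool2d,
    Param,
    ReLU,
    Sequential,
)

__all__ = [
    "PrimaryNetSpec",
    "SecondaryNetSpec",
    "UNet",
    "RoiClassifier",
    "build_primary",
    "build_secondary",
]


@dataclass
class PrimaryNetSpec:
    """Hyper-parameters of the segmentation U-Net.

    ``depth`` encoder levels give ``2 * depth`` 3x3 encoder convolutions
    (10 at the default depth of 5). ``base_channels`` is the width of the
    first level; widths double per level. The default 64 follows U-Net
    convention; 8 is a practical preset for CPU-scale experiments.
    """

    depth: int = 5
    base_channels: int = 64
    n_classes: int = 2
    input_size: int = 128

    def validate(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.n_classes not in (2, 3):
            raise ValueError("n_classes must be 2 (lesion/background) or 3 (background/FCI/LACI)")
        if self.base_channels < 1:
            raise ValueError("base_channels must be positive")
        if self.input_size % (2 ** (self.depth - 1)) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^(depth-1) = {2 ** (self.depth - 1)}"
            )


@dataclass
class SecondaryNetSpec:
    """Hyper-parameters of the ROI correction classifier.

    The body is five 3x3 convolutions with three 2x2 poolings (64 -> 8).
    ``pooling`` selects average (default) or max pooling. ``head`` selects the
    classification head: ``"conv"`` (two 1x1 convolutions, then global average
    pooling to a single logit; default) or ``"fc"`` (two fully connected layers).
    Either head applies dropout during training. Output is one sigmoid
    probability, interpreted as P(LACI).
    """

    base_channels: int = 16
    pooling: str = "average"
    head: str = "conv"
    dropout_rate: float = 0.5
    input_size: int = 64

    def validate(self) -> None:
        if self.input_size != 64:
            raise ValueError("secondary network input_size must be 64")
        if self.pooling not in ("average", "max"):
            raise ValueError("pooling must be 'average' or 'max'")
        if self.head not in ("conv", "fc"):
            raise ValueError("head must be 'conv' or 'fc'")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.base_channels < 1:
            raise ValueError("base_channels must be positive")


def _conv_block(in_ch: int, out_ch: int, rng, name: str) -> Sequential:
    """Two stacked (3x3 conv + BN + ReLU) units."""
    return Sequential(
        Conv2d(in_ch, out_ch, 3, rng=rng, name=f"{name}.0"),
        BatchNorm2d(out_ch, name=f"{name}.0"),
        ReLU(),
        Conv2d(out_ch, out_ch, 3, rng=rng, name=f"{name}.1"),
        BatchNorm2d(out_ch, name=f"{name}.1"),
        ReLU(),
    )


def _softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class UNet:
    """Encoder-decoder segmentation network with skip connections.

    Encoder: ``depth`` levels of two (3x3 conv + BN + ReLU), 2x2 max-pool
    between levels, channel width doubling per level. Decoder: 2x2 transposed
    convolution halving the channels + BN + ReLU, concatenation with the
    encoder feature map of the same scale, then another double conv block.
    Head: two 1x1 convolutions mapping to ``n_classes`` logits; ``predict_proba``
    applies a per-pixel softmax.
    """

    def __init__(self, spec: PrimaryNetSpec, rng: np.random.Generator | None = None):
        spec.validate()
        rng = rng or np.random.default_rng()
        self.spec = spec
        d, b = spec.depth, spec.base_channels
        widths = [b * 2 ** i for i in range(d)]
        self.enc_blocks = []
        in_ch = 1
        for i, w in enumerate(widths):
            self.enc_blocks.append(_conv_block(in_ch, w, rng, f"enc{i}"))
            in_ch = w
        self.pools = [MaxPool2d() for _ in range(d - 1)]
        self.ups = []
        self.up_bns = []
        self.up_relus = []
        self.dec_blocks = []
        for i in range(d - 2, -1, -1):  # decode from deepest towards full resolution
            self.ups.append(ConvTranspose2d(widths[i + 1], widths[i], rng=rng, name=f"up{i}"))
            self.up_bns.append(BatchNorm2d(widths[i], name=f"up{i}"))
            self.up_relus.append(ReLU())
            self.dec_blocks.append(_conv_block(2 * widths[i], widths[i], rng, f"dec{i}"))
        self.head = Sequential(
            Conv2d(b, b, 1, rng=rng, name="head.0"),
            ReLU(),
            Conv2d(b, spec.n_classes, 1, rng=rng, name="head.1"),
        )
        self._skip_grads: list[np.ndarray] | None = None

    # -- introspection -------------------------------------------------------
    @property
    def n_encoder_convs(self) -> int:
        """Number of 3x3 convolutions on the encoding path."""
        return sum(
            1
            for blk in self.enc_blocks
            for layer in blk.layers
            if isinstance(layer, Conv2d) and layer.kernel == 3
        )

    def params(self) -> list[Param]:
        out = []
        for blk in self.enc_blocks:
            out.extend(blk.params())
        for up, bn, dec in zip(self.ups, self.up_bns, self.dec_blocks):
            out.extend(up.params())
            out.extend(bn.params())
            out.extend(dec.params())
        out.extend(self.head.params())
        return out

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    # -- forward / backward --------------------------------------------------
    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, 1, H, W) -> (N, n_classes, H, W) logits."""
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("expected input of shape (N, 1, H, W)")
        if x.shape[2] % (2 ** (self.spec.depth - 1)) or x.shape[3] % (2 ** (self.spec.depth - 1)):
            raise ValueError("spatial size must be divisible by 2^(depth-1)")
        x = np.asarray(x, dtype=np.float32)
        skips = []
        for i, blk in enumerate(self.enc_blocks):
            x = blk.forward(x, train=train)
            if i < len(self.enc_blocks) - 1:
                skips.append(x)
                x = self.pools[i].forward(x, train=train)
        for j, (up, bn, relu, dec) in enumerate(
            zip(self.ups, self.up_bns, self.up_relus, self.dec_blocks)
        ):
            x = relu.forward(bn.forward(up.forward(x, train=train), train=train), train=train)
            skip = skips[len(skips) - 1 - j]
            x = np.concatenate([skip, x], axis=1)
            x = dec.forward(x, train=train)
        return self.head.forward(x, train=train)

    def backward(self, grad_logits: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(logits)."""
        g = self.head.backward(grad_logits)
        skip_grads = []
        for up, bn, relu, dec in zip(
            reversed(self.ups), reversed(self.up_bns), reversed(self.up_relus), reversed(self.dec_blocks)
        ):
            g = dec.backward(g)
            ch = g.shape[1] // 2
            skip_grads.append(g[:, :ch])
            g = up.backward(bn.backward(relu.backward(g[:, ch:])))
        # skip_grads[0] belongs to the shallowest level (last decoded)
        g = self.enc_blocks[-1].backward(g)
        for i in range(len(self.enc_blocks) - 2, -1, -1):
            g = self.pools[i].backward(g)
            g = g + skip_grads[i]
            g = self.enc_blocks[i].backward(g)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities (softmax over channel axis), eval mode."""
        return _softmax(self.forward_logits(x, train=False), axis=1)

    # -- serialization -------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value.copy() for p in self.params()}
        for i, bn in enumerate(self._batchnorms()):
            state[f"running.{i}.mean"] = bn.running_mean.copy()
            state[f"running.{i}.var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value = np.asarray(state[p.name], dtype=np.float32)
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean = np.asarray(state[f"running.{i}.mean"], dtype=np.float32)
            bn.running_var = np.asarray(state[f"running.{i}.var"], dtype=np.float32)

    def _batchnorms(self):
        out = []
        for blk in self.enc_blocks:
            out.extend(l for l in blk.layers if isinstance(l, BatchNorm2d))
        for bn, dec in zip(self.up_bns, self.dec_blocks):
            out.append(bn)
            out.extend(l for l in dec.layers if isinstance(l, BatchNorm2d))
        return out


class RoiClassifier:
    """Five-convolution CNN scoring a 64x64 T1 ROI as P(LACI).

    Three 2x2 poolings reduce 64 -> 8; the head is either two 1x1 convolutions
    followed by global average pooling (default) or two fully connected layers.
    Dropout regularizes the head during training only.
    """

    def __init__(self, spec: SecondaryNetSpec, rng: np.random.Generator | None = None):
        spec.validate()
        rng = rng or np.random.default_rng()
        self.spec = spec
        c = spec.base_channels
        pool = AvgPool2d if spec.pooling == "average" else MaxPool2d
        body = [
            Conv2d(1, c, 3, rng=rng, name="conv0"),
            BatchNorm2d(c, name="conv0"),
            ReLU(),
            Conv2d(c, c, 3, rng=rng, name="conv1"),
            BatchNorm2d(c, name="conv1"),
            ReLU(),
            pool(),
            Conv2d(c, 2 * c, 3, rng=rng, name="conv2"),
            BatchNorm2d(2 * c, name="conv2"),
            ReLU(),
            pool(),
            Conv2d(2 * c, 2 * c, 3, rng=rng, name="conv3"),
            BatchNorm2d(2 * c, name="conv3"),
            ReLU(),
            pool(),
            Conv2d(2 * c, 4 * c, 3, rng=rng, name="conv4"),
            BatchNorm2d(4 * c, name="conv4"),
            ReLU(),
        ]
        if spec.head == "conv":
            head = [
                Dropout(spec.dropout_rate, rng=rng),
                Conv2d(4 * c, 2 * c, 1, rng=rng, name="head.0"),
                ReLU(),
                Dropout(spec.dropout_rate, rng=rng),
                Conv2d(2 * c, 1, 1, rng=rng, name="head.1"),
                GlobalAvgPool2d(),
            ]
        else:
            head = [
                Flatten(),
                Linear(4 * c * 8 * 8, 64, rng=rng, name="head.0"),
                ReLU(),
                Dropout(spec.dropout_rate, rng=rng),
                Linear(64, 1, rng=rng, name="head.1"),
            ]
        self.net = Sequential(*body, *head)

    def params(self) -> list[Param]:
        return self.net.params()

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, 1, 64, 64) -> (N,) logits."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None, None]
        if x.ndim != 4 or x.shape[1] != 1 or x.shape[2:] != (self.spec.input_size, self.spec.input_size):
            raise ValueError(f"expected ROIs of shape (N, 1, {self.spec.input_size}, {self.spec.input_size})")
        return self.net.forward(x, train=train)[:, 0]

    def backward(self, grad_logits: np.ndarray) -> None:
        self.net.backward(np.asarray(grad_logits, dtype=np.float32)[:, None])

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Sigmoid P(LACI) per ROI, eval mode (dropout disabled)."""
        z = self.forward_logits(x, train=False)
        return 0.5 * (1.0 + np.tanh(0.5 * z))

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value.copy() for p in self.params()}
        for i, bn in enumerate(self._batchnorms()):
            state[f"running.{i}.mean"] = bn.running_mean.copy()
            state[f"running.{i}.var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value = np.asarray(state[p.name], dtype=np.float32)
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean = np.asarray(state[f"running.{i}.mean"], dtype=np.float32)
            bn.running_var = np.asarray(state[f"running.{i}.var"], dtype=np.float32)

    def _batchnorms(self):
        return [l for l in self.net.layers if isinstance(l, BatchNorm2d)]

    def _dropouts(self):
        return [l for l in self.net.layers if isinstance(l, Dropout)]


def build_primary(spec: PrimaryNetSpec | None = None, rng: np.random.Generator | None = None) -> UNet:
    """Build the segmentation network from its spec (randomly initialized)."""
    return UNet(spec or PrimaryNetSpec(), rng=rng)


def build_secondary(spec: SecondaryNetSpec | None = None, rng: np.random.Generator | None = None) -> RoiClassifier:
    """Build the ROI correction classifier from its spec (randomly initialized)."""
    return RoiClassifier(spec or SecondaryNetSpec(), rng=rng)
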