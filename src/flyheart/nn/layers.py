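"""Network building blocks and the two model architectures.

``AttentionUNet`` is a symmetric encoder/decoder segmentation network
with additive attention gates on the skip connections: the gating
signal comes from the upsampled decoder feature map, the gated features
from the encoder skip. Both are projected to an intermediate width by
1x1 convolutions, summed, passed through relu, and collapsed to a
single-channel sigmoid map that multiplicatively re-weights the skip
features before concatenation. Convolution kernels are rectangular
(default 3x7, wide along the horizontal heart-tube axis).

``VideoCNN`` is the keyframe age classifier: the stack of motion-selected
frames enters as input channels, passes through 3 convolution blocks
(two 3x3 convolutions then 2x2 max pooling each), is flattened,
concatenated with the inter-keyframe durations, and fed to three dense
layers ending in a single logit.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, conv2d, maxpool2, relu, sigmoid, upsample2

__all__ = ["Module", "Conv2d", "Linear", "AttentionUNet", "VideoCNN"]


class Module:
    """Base class: recursively collects parameter tensors."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state does not match model parameters")
        for p, s in zip(params, state):
            p.data = s.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_conv(rng: np.random.Generator, f: int, c: int, kh: int, kw: int) -> Tensor:
    std = np.sqrt(2.0 / (c * kh * kw))
    return Tensor(rng.normal(0.0, std, size=(f, c, kh, kw)), requires_grad=True)


class Conv2d(Module):
    def __init__(self, rng, cin: int, cout: int, kernel=(3, 3)):
        self.w = _he_conv(rng, cout, cin, *kernel)
        self.b = Tensor(np.zeros(cout), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b)


class Linear(Module):
    def __init__(self, rng, din: int, dout: int):
        std = np.sqrt(2.0 / din)
        self.w = Tensor(rng.normal(0.0, std, size=(din, dout)), requires_grad=True)
        self.b = Tensor(np.zeros(dout), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class _DoubleConv(Module):
    def __init__(self, rng, cin, cout, kernel):
        self.c1 = Conv2d(rng, cin, cout, kernel)
        self.c2 = Conv2d(rng, cout, cout, kernel)

    def forward(self, x):
        return relu(self.c2(relu(self.c1(x))))


class _AttentionGate(Module):
    """Additive attention: psi = sigma(w_psi . relu(w_x x + w_g g))."""

    def __init__(self, rng, channels: int):
        inter = max(channels // 2, 1)
        self.theta_x = Conv2d(rng, channels, inter, (1, 1))
        self.phi_g = Conv2d(rng, channels, inter, (1, 1))
        self.psi = Conv2d(rng, inter, 1, (1, 1))

    def forward(self, skip: Tensor, gate: Tensor) -> Tensor:
        att = sigmoid(self.psi(relu(self.theta_x(skip) + self.phi_g(gate))))
        return skip * att


class AttentionUNet(Module):
    """Attention U-Net for single-channel (wall vs background) segmentation.

    Parameters
    ----------
    filters : per-level channel counts, strictly increasing (default
        8, 16, 32, 64, 128). Spatial input dims must be divisible by
        2**(levels-1).
    kernel : rectangular convolution kernel (rows, cols), odd sizes.
    attention_gates : disable to fall back to a plain U-Net.
    """

    def __init__(self, in_channels=3, filters=(8, 16, 32, 64, 128),
                 kernel=(3, 7), attention_gates=True, seed=0):
        filters = tuple(int(f) for f in filters)
        if any(b <= a for a, b in zip(filters, filters[1:])):
            raise ValueError("filters must be strictly increasing per level")
        rng = np.random.default_rng(seed)
        self.filters = filters
        self.attention_gates = attention_gates
        self.encoders = [
            _DoubleConv(rng, cin, cout, kernel)
            for cin, cout in zip((in_channels,) + filters[:-1], filters)
        ]
        # decoder mirrors the encoder; upsampled features are reduced to the
        # skip width by a 1x1 conv so gate and skip channel counts match
        self.up_reduce = [
            Conv2d(rng, filters[i + 1], filters[i], (1, 1))
            for i in range(len(filters) - 1)
        ]
        self.gates = [
            _AttentionGate(rng, filters[i]) if attention_gates else None
            for i in range(len(filters) - 1)
        ]
        self.decoders = [
            _DoubleConv(rng, 2 * filters[i], filters[i], kernel)
            for i in range(len(filters) - 1)
        ]
        self.head = Conv2d(rng, filters[0], 1, (1, 1))

    def parameters(self):
        params = []
        for group in (self.encoders, self.up_reduce, self.gates, self.decoders,
                      [self.head]):
            for m in group:
                if m is not None:
                    params.extend(m.parameters())
        return params

    def forward(self, x: Tensor) -> Tensor:
        """Return per-pixel wall logits of shape (N, 1, H, W)."""
        h, w = x.shape[2], x.shape[3]
        factor = 2 ** (len(self.filters) - 1)
        if h % factor or w % factor:
            raise ValueError(
                f"spatial dims {h}x{w} must be divisible by {factor}"
            )
        skips = []
        for enc in self.encoders[:-1]:
            x = enc(x)
            skips.append(x)
            x = maxpool2(x)
        x = self.encoders[-1](x)
        for i in reversed(range(len(self.decoders))):
            g = self.up_reduce[i](upsample2(x))
            skip = skips[i]
            if self.gates[i] is not None:
                skip = self.gates[i](skip, g)
            x = self.decoders[i](concat([g, skip], axis=1))
        return self.head(x)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Sigmoid wall probabilities for a (N, C, H, W) batch."""
        logits = self.forward(Tensor(x)).data[:, 0]
        return 1.0 / (1.0 + np.exp(-np.clip(logits, -60, 60)))


class VideoCNN(Module):
    """Keyframe video age classifier (frames as channels + durations)."""

    def __init__(self, n_frames=96, frame_shape=(32, 24), conv_channels=(8, 16, 32),
                 dense=(64, 32), seed=0):
        rng = np.random.default_rng(seed)
        h, w = frame_shape
        if h % 8 or w % 8:
            raise ValueError("frame dims must be divisible by 8 (3 pooling stages)")
        self.blocks = []
        cin = n_frames
        for cout in conv_channels:
            self.blocks.append(_DoubleConv(rng, cin, cout, (3, 3)))
            cin = cout
        flat = conv_channels[-1] * (h // 8) * (w // 8)
        self.fc1 = Linear(rng, flat + (n_frames - 1), dense[0])
        self.fc2 = Linear(rng, dense[0], dense[1])
        self.fc3 = Linear(rng, dense[1], 1)
        self.n_frames = n_frames
        self.frame_shape = (h, w)

    def forward(self, frames: Tensor, durations: Tensor) -> Tensor:
        """Return (N,) logits for batches of keyframe stacks + durations."""
        x = frames
        for block in self.blocks:
            x = maxpool2(block(x))
        n = x.shape[0]
        x = x.reshape(n, -1)
        x = concat([x, durations], axis=1)
        x = relu(self.fc1(x))
        x = relu(self.fc2(x))
        return self.fc3(x).reshape(n)
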