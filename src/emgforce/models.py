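"""The three force-regression architectures.

* **CNN** — the Q-point sample is reshaped row-major to a sqrt(Q) x sqrt(Q)
  image, passed through conv(ReLU, batch-norm) + max-pool blocks, flattened,
  dropped out, and mapped by one linear layer back to Q outputs (force
  estimation cast as image-to-image translation).
* **LSTM** — the sample is fed as Q/frame_size timesteps of frame_size
  features to an LSTM; the full output sequence is flattened and encoded to
  Q points by a fully connected layer.
* **C-LSTM** — a 1-D strided convolution front-end extracts a higher-level
  feature sequence which goes through the LSTM, then the flattened output
  is encoded to Q points.

The output head is linear everywhere: the RMSE% loss is computed on raw
predictions, which may over/undershoot [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn


@dataclass(frozen=True)
class ConvBlockSpec:
    n_filters: int
    kernel: int = 3
    stride: int = 1
    pool: int = 2              # max-pool size; 1 disables pooling
    batch_norm: bool = True
    dropout_rate: float = 0.0

    def __post_init__(self):
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class LSTMSpec:
    hidden_units: int = 128
    n_layers: int = 1
    frame_size: int = 1        # samples per timestep

    def __post_init__(self):
        if self.hidden_units < 1 or self.n_layers < 1 or self.frame_size < 1:
            raise ValueError("LSTMSpec fields must be positive")


#: defaults tuned on the development set at desk scale
CNN_BLOCKS_DEFAULT = (ConvBlockSpec(16), ConvBlockSpec(32), ConvBlockSpec(64))
CLSTM_FRONT_DEFAULT = ConvBlockSpec(32, kernel=16, stride=8, pool=1)


@dataclass
class Model:
    family: str
    Q: int
    net: nn.Sequential
    meta: dict = field(default_factory=dict)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Predict a force window per sample row; (B, Q) in, (B, Q) out."""
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite values in the model input")
        squeeze = x.ndim == 1
        if squeeze:
            x = x[None, :]
        out = self.net.forward(x, training=training)
        return out[0] if squeeze else out

    def n_parameters(self) -> int:
        return self.net.n_parameters()


def build_cnn(Q: int, blocks: tuple[ConvBlockSpec, ...] = CNN_BLOCKS_DEFAULT,
              dropout_rate: float = 0.5, seed: int = 0) -> Model:
    """CNN over the square-reshaped sample; requires Q to be a perfect square."""
    side = math.isqrt(Q)
    if side * side != Q:
        raise ValueError(f"Q={Q} is not a perfect square")
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = [nn.Reshape((1, side, side))]
    in_ch, h = 1, side
    for blk in blocks:
        if blk.stride != 1:
            raise ValueError("CNN blocks use stride 1; pooling does the downsampling")
        layers.append(nn.Conv2D(in_ch, blk.n_filters, blk.kernel, rng, padding="same"))
        if blk.batch_norm:
            layers.append(nn.BatchNorm(blk.n_filters))
        layers.append(nn.ReLU())
        if blk.pool > 1:
            layers.append(nn.MaxPool2D(blk.pool))
            h //= blk.pool
        in_ch = blk.n_filters
        if h < 1:
            raise ValueError("pooling reduced the feature map below 1x1")
    layers.append(nn.Flatten())
    if dropout_rate > 0:
        layers.append(nn.Dropout(dropout_rate, rng))
    layers.append(nn.Dense(in_ch * h * h, Q, rng))
    return Model("cnn", Q, nn.Sequential(layers),
                 meta={"blocks": blocks, "dropout": dropout_rate, "seed": seed})


def build_lstm(Q: int, spec: LSTMSpec = LSTMSpec(), seed: int = 0) -> Model:
    """LSTM over the Q-point sequence; whole output sequence feeds the head."""
    if Q % spec.frame_size:
        raise ValueError(f"frame_size {spec.frame_size} does not divide Q={Q}")
    T = Q // spec.frame_size
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = [nn.Reshape((T, spec.frame_size))]
    in_f = spec.frame_size
    for _ in range(spec.n_layers):
        layers.append(nn.LSTM(in_f, spec.hidden_units, rng))
        in_f = spec.hidden_units
    layers.append(nn.Flatten())
    layers.append(nn.Dense(T * spec.hidden_units, Q, rng))
    return Model("lstm", Q, nn.Sequential(layers), meta={"spec": spec, "seed": seed})


def build_clstm(Q: int, front: ConvBlockSpec = CLSTM_FRONT_DEFAULT,
                spec: LSTMSpec = LSTMSpec(hidden_units=64), seed: int = 0) -> Model:
    """Strided 1-D conv front-end, LSTM, flatten, linear head to Q points."""
    if front.kernel > Q:
        raise ValueError(f"front kernel {front.kernel} exceeds Q={Q}")
    T = nn.Conv1D.out_len(Q, front.kernel, front.stride)
    if T < 1:
        raise ValueError("convolution front-end produced an empty sequence")
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = [nn.Reshape((1, Q)),
                              nn.Conv1D(1, front.n_filters, front.kernel,
                                        front.stride, rng)]
    if front.batch_norm:
        layers.append(nn.BatchNorm(front.n_filters))
    layers.append(nn.ReLU())

    class _ToSequence(nn.Layer):
        # (B, C, T) -> (B, T, C)
        def forward(self, x, training=False):
            return x.transpose(0, 2, 1)

        def backward(self, grad):
            return grad.transpose(0, 2, 1)

    layers.append(_ToSequence())
    in_f = front.n_filters
    for _ in range(spec.n_layers):
        layers.append(nn.LSTM(in_f, spec.hidden_units, rng))
        in_f = spec.hidden_units
    layers.append(nn.Flatten())
    layers.append(nn.Dense(T * spec.hidden_units, Q, rng))
    return Model("clstm", Q, nn.Sequential(layers),
                 meta={"front": front, "spec": spec, "seed": seed})


def build_model(family: str, Q: int, seed: int = 0, **kwargs) -> Model:
    """Dispatch on family name: ``cnn`` | ``lstm`` | ``clstm``."""
    builders = {"cnn": build_cnn, "lstm": build_lstm, "clstm": build_clstm}
    if family not in builders:
        raise ValueError(f"unknown model family {family!r}")
    return builders[family](Q, seed=seed, **kwargs)
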