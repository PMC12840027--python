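"""The CNN-LSTM-MHA drying predictor.

The network maps a rolling window of normalized process features (current
moisture content, drying time, drying rate DR, shrinkage rate SR, total
color difference dE and, in the default conditioning mode, the next-stage
temperature setpoint) to the normalized next-stage (DR, SR, dE).

Pipeline: 1-D convolution (kernel 3, padding 1, ReLU) -> max pool (width 2,
stride 1, same length) -> LSTM -> multi-head self-attention with a residual
connection -> LSTM -> multi-head self-attention with a residual connection
-> last-step hidden state -> affine head to 3 outputs.  Attention and
convolution blocks are interleaved with the recurrent passes so that local
feature extraction and cross-time-step correlation both act on the hidden
sequence.

The printed hidden size (256) is not divisible by the printed head count
(6); attention therefore projects internally to the largest multiple of the
head count not exceeding the hidden size (256 -> 252 = 6 x 42) and the
output projection maps back to the hidden size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .layers import (
    AttentionWeights,
    conv1d_extract,
    lstm_sequence,
    multihead_attention,
    pool1d,
)

__all__ = ["ModelSpec", "CnnLstmMha", "glorot_uniform"]

#: Feature order of a window row in the default (temperature-conditioned) mode.
FEATURE_NAMES = ("M_db", "t_min", "DR", "SR_pct", "dE", "T_next")
#: Targets predicted for the next stage.
TARGET_NAMES = ("DR", "SR_pct", "dE")


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Uniform init scaled by fan-in + fan-out (first/last axis sizes)."""
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


@dataclass
class ModelSpec:
    """Hyperparameters of the predictor.

    ``input_features`` is 5 (moisture, time, DR, SR, dE) in strict mode or 6
    with the next-stage temperature appended; ``output`` is always 3.
    """

    input_features: int = 6
    conv_filters: int = 32
    kernel: int = 3
    hidden: int = 256
    heads: int = 6
    output: int = 3
    attn_dim: int | None = None
    seed: int = 0
    dtype: str = "float64"  # "float32" roughly halves training time

    def __post_init__(self) -> None:
        if self.attn_dim is None:
            self.attn_dim = (self.hidden // self.heads) * self.heads
        if self.attn_dim % self.heads != 0:
            raise ValueError("attn_dim must be divisible by the number of heads")
        if self.output != 3:
            raise ValueError("the predictor always emits (DR, SR, dE)")
        if self.kernel % 2 != 1:
            raise ValueError("kernel size must be odd (padding keeps length)")

    def to_dict(self) -> dict:
        return {
            "input_features": self.input_features,
            "conv_filters": self.conv_filters,
            "kernel": self.kernel,
            "hidden": self.hidden,
            "heads": self.heads,
            "output": self.output,
            "attn_dim": self.attn_dim,
            "seed": self.seed,
            "dtype": self.dtype,
        }


class CnnLstmMha:
    """Trainable CNN-LSTM-MHA network (see module docstring for the layout)."""

    name = "CNN-LSTM-MHA"

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        h, c, k = spec.hidden, spec.conv_filters, spec.kernel
        d = spec.attn_dim // spec.heads
        p: dict[str, Tensor] = {}

        dt = np.dtype(spec.dtype)

        def par(name: str, shape: tuple[int, ...]) -> Tensor:
            t = Tensor(glorot_uniform(rng, shape).astype(dt), requires_grad=True)
            p[name] = t
            return t

        def zeros(name: str, shape: tuple[int, ...]) -> Tensor:
            t = Tensor(np.zeros(shape, dtype=dt), requires_grad=True)
            p[name] = t
            return t

        par("conv.W", (k, spec.input_features, c))
        zeros("conv.b", (c,))
        par("lstm1.W", (c + h, 4 * h))
        zeros("lstm1.b", (4 * h,))
        par("lstm2.W", (2 * h, 4 * h))
        zeros("lstm2.b", (4 * h,))
        for blk in ("mha1", "mha2"):
            for head in range(spec.heads):
                par(f"{blk}.q{head}", (h, d))
                par(f"{blk}.k{head}", (h, d))
                par(f"{blk}.v{head}", (h, d))
            par(f"{blk}.o", (spec.attn_dim, h))
        par("head.W", (h, spec.output))
        zeros("head.b", (spec.output,))
        self.params = p

    # ------------------------------------------------------------------ api
    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def _attention(self, blk: str) -> AttentionWeights:
        p, heads = self.params, self.spec.heads
        return AttentionWeights(
            w_q=[p[f"{blk}.q{i}"] for i in range(heads)],
            w_k=[p[f"{blk}.k{i}"] for i in range(heads)],
            w_v=[p[f"{blk}.v{i}"] for i in range(heads)],
            w_o=p[f"{blk}.o"],
        )

    def forward(self, x: Tensor) -> Tensor:
        """Map windows (batch, w, input_features) -> normalized (batch, 3)."""
        x = Tensor._lift(x)
        if x.ndim != 3 or x.shape[2] != self.spec.input_features:
            raise ValueError(
                f"window must be (batch, w, {self.spec.input_features}), got {x.shape}"
            )
        p, h = self.params, self.spec.hidden
        z = conv1d_extract(x, p["conv.W"], p["conv.b"], activation="relu")
        z = pool1d(z)
        z = lstm_sequence(z, p["lstm1.W"], p["lstm1.b"], h)
        z = z + multihead_attention(z, self._attention("mha1"))
        z = lstm_sequence(z, p["lstm2.W"], p["lstm2.b"], h)
        z = z + multihead_attention(z, self._attention("mha2"))
        last = z[:, -1, :]
        return last @ p["head.W"] + p["head.b"]

    def predict(self, windows: np.ndarray) -> np.ndarray:
        """Inference on a numpy batch; returns normalized (batch, 3)."""
        dt = self.params["head.W"].data.dtype
        out = self.forward(Tensor(np.asarray(windows, dtype=dt))).data
        return np.asarray(out, dtype=float)
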