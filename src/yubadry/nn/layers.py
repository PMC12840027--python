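"""Building blocks of the drying predictor: LSTM cell, 1-D convolution,
pooling, and (multi-head) scaled dot-product attention.

Two parallel surfaces are provided for the LSTM cell:

* :func:`lstm_cell_step` — plain-numpy, textbook gate equations, used as the
  mathematically transparent reference and for single-step inspection;
* :func:`lstm_sequence` — the autodiff path used inside trainable models,
  parameterized by a single fused gate matrix.

:func:`fuse_gate_weights` / :func:`split_gate_weights` convert between the
two parameterizations; both paths are required (and tested) to agree.

Gate blocks are ordered ``[forget, input, candidate, output]`` everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concatenate, maximum, softmax

__all__ = [
    "LstmCellWeights",
    "FusedLstmWeights",
    "AttentionWeights",
    "lstm_cell_step",
    "lstm_cell_step_fused",
    "fuse_gate_weights",
    "split_gate_weights",
    "lstm_sequence",
    "conv1d_extract",
    "pool1d",
    "scaled_dot_attention",
    "multihead_attention",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _mm3(x: Tensor, W: Tensor) -> Tensor:
    """(batch, steps, f) @ (f, g) as one flat 2-D GEMM instead of a stack
    of per-sample multiplies (much faster for long batches)."""
    batch, steps, f = x.shape
    return (x.reshape(batch * steps, f) @ W).reshape(batch, steps, W.shape[-1])


# --------------------------------------------------------------------- LSTM
@dataclass
class LstmCellWeights:
    """Separate gate parameterization.

    Each gate matrix has shape ``(hidden, hidden + input)`` and acts on the
    concatenated column vector ``[h_prev, x]``; biases have length ``hidden``.
    """

    W_f: np.ndarray
    W_i: np.ndarray
    W_C: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_C: np.ndarray
    b_o: np.ndarray

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.W_f, self.W_i, self.W_C, self.W_o)}
        if len(shapes) != 1:
            raise ValueError("gate matrices must share one shape")
        h = self.W_f.shape[0]
        if self.W_f.shape[1] <= h:
            raise ValueError("gate matrices must be (hidden, hidden + input)")
        for b in (self.b_f, self.b_i, self.b_C, self.b_o):
            if b.shape != (h,):
                raise ValueError("biases must have length hidden")

    @property
    def hidden_size(self) -> int:
        return self.W_f.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_f.shape[1] - self.W_f.shape[0]


@dataclass
class FusedLstmWeights:
    """All four gates stacked into one ``(4*hidden, hidden + input)`` matrix."""

    W: np.ndarray
    b: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.W.shape[0] // 4


def lstm_cell_step(
    x: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray, w: LstmCellWeights
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM step: forget/input/candidate/output gates, state update.

    f = sigma(W_f [h,x] + b_f),  i = sigma(W_i [h,x] + b_i),
    C' = tanh(W_C [h,x] + b_C),  c = f*c_prev + i*C',
    o = sigma(W_o [h,x] + b_o),  h = o * tanh(c).
    """
    x = np.asarray(x, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    c_prev = np.asarray(c_prev, dtype=float)
    if x.shape[-1] != w.input_size or h_prev.shape[-1] != w.hidden_size:
        raise ValueError(
            f"expected input {w.input_size} and hidden {w.hidden_size}, "
            f"got {x.shape[-1]} and {h_prev.shape[-1]}"
        )
    hx = np.concatenate([h_prev, x], axis=-1)
    f = _sigmoid(hx @ w.W_f.T + w.b_f)
    i = _sigmoid(hx @ w.W_i.T + w.b_i)
    g = np.tanh(hx @ w.W_C.T + w.b_C)
    c = f * c_prev + i * g
    o = _sigmoid(hx @ w.W_o.T + w.b_o)
    h = o * np.tanh(c)
    return h, c


def fuse_gate_weights(w: LstmCellWeights) -> FusedLstmWeights:
    """Stack the four gate matrices/biases into a single fused block."""
    return FusedLstmWeights(
        W=np.vstack([w.W_f, w.W_i, w.W_C, w.W_o]),
        b=np.concatenate([w.b_f, w.b_i, w.b_C, w.b_o]),
    )


def split_gate_weights(fused: FusedLstmWeights) -> LstmCellWeights:
    """Inverse of :func:`fuse_gate_weights`."""
    h = fused.hidden_size
    W, b = fused.W, fused.b
    return LstmCellWeights(
        W_f=W[:h], W_i=W[h : 2 * h], W_C=W[2 * h : 3 * h], W_o=W[3 * h :],
        b_f=b[:h], b_i=b[h : 2 * h], b_C=b[2 * h : 3 * h], b_o=b[3 * h :],
    )


def lstm_cell_step_fused(
    x: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray, fused: FusedLstmWeights
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM step through the fused matrix; slices out the four gates."""
    h = fused.hidden_size
    hx = np.concatenate([np.asarray(h_prev, float), np.asarray(x, float)], axis=-1)
    z = hx @ fused.W.T + fused.b
    f = _sigmoid(z[..., :h])
    i = _sigmoid(z[..., h : 2 * h])
    g = np.tanh(z[..., 2 * h : 3 * h])
    c = f * np.asarray(c_prev, float) + i * g
    o = _sigmoid(z[..., 3 * h :])
    return o * np.tanh(c), c


def lstm_sequence(x: Tensor, W: Tensor, b: Tensor, hidden: int) -> Tensor:
    """Run a fused-weight LSTM over a batch of sequences.

    Parameters
    ----------
    x : Tensor, shape (batch, steps, features)
    W : Tensor, shape (hidden + features, 4*hidden)
        Row-vector convention: ``z = [h, x_t] @ W + b``; gate blocks along
        the last axis in fused order [f, i, C', o].
    b : Tensor, shape (4*hidden,)

    Returns the full hidden-state sequence, shape (batch, steps, hidden).
    Initial hidden and cell states are zero.
    """
    x = Tensor._lift(x)
    batch, steps, feats = x.shape
    H = hidden
    Wh = W.data[:H, :]
    Wx = W.data[H:, :]
    if Wx.shape[0] != feats:
        raise ValueError(f"weight expects {Wx.shape[0]} input features, got {feats}")

    # fused forward: one big input-side GEMM, then the recurrent loop,
    # caching gate activations for the analytic backward pass (BPTT)
    zx = x.data.reshape(batch * steps, feats) @ Wx
    zx = zx.reshape(batch, steps, 4 * H) + b.data
    F = np.empty((batch, steps, H), dtype=zx.dtype); I = np.empty_like(F)
    G = np.empty_like(F); O = np.empty_like(F)
    TC = np.empty_like(F)                      # tanh(c_t)
    C_prev = np.empty_like(F); H_prev = np.empty_like(F)
    h = np.zeros((batch, H), dtype=zx.dtype); c = np.zeros_like(h)
    out_data = np.empty((batch, steps, H), dtype=zx.dtype)
    for t in range(steps):
        H_prev[:, t] = h
        C_prev[:, t] = c
        z = h @ Wh + zx[:, t]
        f = _sigmoid(z[:, :H]); i = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H]); o = _sigmoid(z[:, 3 * H :])
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        F[:, t], I[:, t], G[:, t], O[:, t], TC[:, t] = f, i, g, o, tc
        out_data[:, t] = h

    def backward(dH_all: np.ndarray) -> None:
        dzx = np.empty((batch, steps, 4 * H), dtype=zx.dtype)
        dWh = np.zeros_like(Wh)
        dh_next = np.zeros((batch, H), dtype=zx.dtype); dc_next = dh_next.copy()
        for t in range(steps - 1, -1, -1):
            dh = dH_all[:, t] + dh_next
            f, i, g, o, tc = F[:, t], I[:, t], G[:, t], O[:, t], TC[:, t]
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            dz = dzx[:, t]
            dz[:, :H] = (dc * C_prev[:, t]) * f * (1.0 - f)
            dz[:, H : 2 * H] = (dc * g) * i * (1.0 - i)
            dz[:, 2 * H : 3 * H] = (dc * i) * (1.0 - g * g)
            dz[:, 3 * H :] = do * o * (1.0 - o)
            dh_next = dz @ Wh.T
            dc_next = dc * f
            dWh += H_prev[:, t].T @ dz
        dzx_flat = dzx.reshape(batch * steps, 4 * H)
        if x.requires_grad or x._parents:
            x._accumulate((dzx_flat @ Wx.T).reshape(batch, steps, feats))
        if W.requires_grad or W._parents:
            dW = np.empty_like(W.data)
            dW[:H] = dWh
            dW[H:] = x.data.reshape(batch * steps, feats).T @ dzx_flat
            W._accumulate(dW)
        if b.requires_grad or b._parents:
            b._accumulate(dzx_flat.sum(axis=0))

    tracked = tuple(t for t in (x, W, b) if t.requires_grad or t._parents)
    if not tracked:
        return Tensor(out_data)
    return Tensor(out_data, _parents=tracked, _backward=backward)


# ------------------------------------------------------------------ CNN part
def conv1d_extract(x: Tensor, kernel: Tensor, bias: Tensor | None = None,
                   activation: str = "relu") -> Tensor:
    """Same-length 1-D convolution over the time axis.

    ``x`` is (batch, steps, channels_in); ``kernel`` is (k, channels_in,
    channels_out) with odd ``k``; zero padding of (k-1)/2 on both ends keeps
    the output aligned one-row-per-time-step with the input.
    """
    x = Tensor._lift(x)
    k = kernel.shape[0]
    if k % 2 != 1:
        raise ValueError("kernel size must be odd to preserve sequence length")
    pad = (k - 1) // 2
    batch, steps, cin = x.shape
    if kernel.shape[1] != cin:
        raise ValueError(f"kernel expects {kernel.shape[1]} input channels, got {cin}")
    if pad:
        zeros = Tensor(np.zeros((batch, pad, cin), dtype=x.data.dtype))
        xp = concatenate([zeros, x, zeros], axis=1)
    else:
        xp = x
    out = _mm3(xp[:, 0:steps, :], kernel[0])
    for tap in range(1, k):
        out = out + _mm3(xp[:, tap : tap + steps, :], kernel[tap])
    if bias is not None:
        out = out + bias
    if activation == "relu":
        out = out.relu()
    elif activation == "identity":
        pass
    else:
        raise ValueError(f"unknown activation {activation!r}")
    return out


def pool1d(x: Tensor) -> Tensor:
    """Max pooling, width 2, stride 1, same length.

    The final time step is paired with a replicate of itself so the pooled
    sequence keeps one row per sampling instant (the controller relies on
    the 1-min alignment).
    """
    x = Tensor._lift(x)
    if x.shape[1] < 1:
        raise ValueError("cannot pool an empty sequence")
    shifted = concatenate([x[:, 1:, :], x[:, -1:, :]], axis=1)
    return maximum(x, shifted)


# ------------------------------------------------------------------ attention
def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor) -> Tensor:
    """softmax(Q K^T / sqrt(d)) V, applied along the last two axes."""
    q, k, v = Tensor._lift(q), Tensor._lift(k), Tensor._lift(v)
    d = q.shape[-1]
    if k.shape[-1] != d:
        raise ValueError("Q and K must share the key dimension")
    if k.shape[-2] != v.shape[-2]:
        raise ValueError("K and V must share the sequence length")
    scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d))
    return softmax(scores, axis=-1) @ v


@dataclass
class AttentionWeights:
    """Per-head projections plus the output projection of multi-head attention.

    ``w_q[i]``, ``w_k[i]``, ``w_v[i]`` each map model dim -> per-head dim d;
    ``w_o`` maps the concatenated ``h*d`` back to the model dimension.
    """

    w_q: list
    w_k: list
    w_v: list
    w_o: Tensor

    def __post_init__(self) -> None:
        if not (len(self.w_q) == len(self.w_k) == len(self.w_v)):
            raise ValueError("per-head projection lists must have equal length")
        if len(self.w_q) < 1:
            raise ValueError("at least one head required")

    @property
    def heads(self) -> int:
        return len(self.w_q)

    @property
    def head_dim(self) -> int:
        return self.w_q[0].shape[-1]


def multihead_attention_composed(x: Tensor, w: AttentionWeights) -> Tensor:
    """Reference composition of multi-head attention from the individual
    ops: per-head projected :func:`scaled_dot_attention`, concatenation,
    output projection.  Kept as the transparent two-route counterpart of
    the fused :func:`multihead_attention`."""
    x = Tensor._lift(x)
    heads = []
    for wq, wk, wv in zip(w.w_q, w.w_k, w.w_v):
        heads.append(scaled_dot_attention(_mm3(x, wq), _mm3(x, wk), _mm3(x, wv)))
    return _mm3(concatenate(heads, axis=-1), w.w_o)


def multihead_attention(x: Tensor, w: AttentionWeights) -> Tensor:
    """Self-attention with h parallel heads: concat(H_1..H_h) W_O.

    ``x`` is (batch, steps, model_dim); each head computes scaled dot-product
    attention on its own linear projections of x.  Implemented as one fused
    graph op with an analytic backward pass (numerically identical to
    :func:`multihead_attention_composed`, which the tests verify).
    """
    x = Tensor._lift(x)
    batch, steps, dm = x.shape
    heads, d = w.heads, w.head_dim
    dt = x.data.dtype
    Wq = np.concatenate([np.asarray(m.data, dt) for m in w.w_q], axis=1)  # (dm, h*d)
    Wk = np.concatenate([np.asarray(m.data, dt) for m in w.w_k], axis=1)
    Wv = np.concatenate([np.asarray(m.data, dt) for m in w.w_v], axis=1)
    Wo = np.asarray(w.w_o.data, dt)
    xf = x.data.reshape(batch * steps, dm)

    def _split_heads(a: np.ndarray) -> np.ndarray:  # (B*w, h*d) -> (B, h, w, d)
        return a.reshape(batch, steps, heads, d).transpose(0, 2, 1, 3)

    Q = _split_heads(xf @ Wq)
    K = _split_heads(xf @ Wk)
    V = _split_heads(xf @ Wv)
    scale = 1.0 / np.sqrt(d)
    scores = np.matmul(Q, K.swapaxes(-1, -2)) * scale
    scores -= scores.max(axis=-1, keepdims=True)
    P = np.exp(scores)
    P /= P.sum(axis=-1, keepdims=True)
    ctx = np.matmul(P, V)                                # (B, h, w, d)
    concat = ctx.transpose(0, 2, 1, 3).reshape(batch * steps, heads * d)
    out_data = (concat @ Wo).reshape(batch, steps, Wo.shape[-1])

    def backward(g: np.ndarray) -> None:
        gf = g.reshape(batch * steps, -1)
        d_concat = gf @ Wo.T
        d_ctx = _split_heads(d_concat)
        dP = np.matmul(d_ctx, V.swapaxes(-1, -2))
        dV = np.matmul(P.swapaxes(-1, -2), d_ctx)
        dS = P * (dP - (dP * P).sum(axis=-1, keepdims=True))
        dS *= scale
        dQ = np.matmul(dS, K)
        dK = np.matmul(dS.swapaxes(-1, -2), Q)

        def _merge(a: np.ndarray) -> np.ndarray:  # (B, h, w, d) -> (B*w, h*d)
            return a.transpose(0, 2, 1, 3).reshape(batch * steps, heads * d)

        dQf, dKf, dVf = _merge(dQ), _merge(dK), _merge(dV)
        if x.requires_grad or x._parents:
            dx = dQf @ Wq.T + dKf @ Wk.T + dVf @ Wv.T
            x._accumulate(dx.reshape(batch, steps, dm))
        dWq = xf.T @ dQf
        dWk = xf.T @ dKf
        dWv = xf.T @ dVf
        for i in range(heads):
            sl = slice(i * d, (i + 1) * d)
            if w.w_q[i].requires_grad:
                w.w_q[i]._accumulate(dWq[:, sl])
            if w.w_k[i].requires_grad:
                w.w_k[i]._accumulate(dWk[:, sl])
            if w.w_v[i].requires_grad:
                w.w_v[i]._accumulate(dWv[:, sl])
        if w.w_o.requires_grad or w.w_o._parents:
            w.w_o._accumulate(concat.T @ gf)

    tracked = tuple(t for t in (x, w.w_o, *w.w_q, *w.w_k, *w.w_v)
                    if t.requires_grad or t._parents)
    if not tracked:
        return Tensor(out_data)
    return Tensor(out_data, _parents=tracked, _backward=backward)
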