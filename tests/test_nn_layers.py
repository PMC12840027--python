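"""LSTM cell equations, fused-weight equivalence, convolution, pooling,
and scaled dot-product / multi-head attention."""

import numpy as np
import pytest

from yubadry.nn import Tensor
from yubadry.nn.layers import (
    AttentionWeights,
    LstmCellWeights,
    conv1d_extract,
    fuse_gate_weights,
    lstm_cell_step,
    lstm_cell_step_fused,
    lstm_sequence,
    multihead_attention,
    multihead_attention_composed,
    pool1d,
    scaled_dot_attention,
    split_gate_weights,
)


def random_cell(rng, hidden=3, inputs=2, scale=0.5) -> LstmCellWeights:
    s = (hidden, hidden + inputs)
    return LstmCellWeights(
        W_f=rng.normal(size=s) * scale, W_i=rng.normal(size=s) * scale,
        W_C=rng.normal(size=s) * scale, W_o=rng.normal(size=s) * scale,
        b_f=rng.normal(size=hidden) * scale, b_i=rng.normal(size=hidden) * scale,
        b_C=rng.normal(size=hidden) * scale, b_o=rng.normal(size=hidden) * scale,
    )


def zero_cell(hidden=3, inputs=2) -> LstmCellWeights:
    s = (hidden, hidden + inputs)
    z = np.zeros
    return LstmCellWeights(W_f=z(s), W_i=z(s), W_C=z(s), W_o=z(s),
                           b_f=z(hidden), b_i=z(hidden), b_C=z(hidden), b_o=z(hidden))


class TestLstmCellStep:
    def test_zero_weights_zero_cell(self):
        h, c = lstm_cell_step(np.ones(2), np.zeros(3), np.zeros(3), zero_cell())
        np.testing.assert_array_equal(h, 0.0)
        np.testing.assert_array_equal(c, 0.0)

    def test_zero_weights_nonzero_cell(self):
        """With all weights zero: f = i = o = 1/2, C' = 0, so
        c_next = c/2 and h = tanh(c/2)/2, element by element."""
        c_prev = np.array([0.4, -1.2, 2.0])
        h, c = lstm_cell_step(np.ones(2), np.zeros(3), c_prev, zero_cell())
        np.testing.assert_allclose(c, 0.5 * c_prev, atol=1e-15)
        np.testing.assert_allclose(h, 0.5 * np.tanh(0.5 * c_prev), atol=1e-15)

    def test_matches_reference_recurrence(self, rng):
        """Independently coded gate-by-gate recurrence over several steps."""
        w = random_cell(rng)
        sig = lambda v: 1.0 / (1.0 + np.exp(-v))
        h = np.zeros(3)
        c = np.zeros(3)
        h_ref = np.zeros(3)
        c_ref = np.zeros(3)
        for _ in range(8):
            x = rng.normal(size=2)
            h, c = lstm_cell_step(x, h, c, w)
            hx = np.concatenate([h_ref, x])
            f = sig(w.W_f @ hx + w.b_f)
            i = sig(w.W_i @ hx + w.b_i)
            g = np.tanh(w.W_C @ hx + w.b_C)
            c_ref = f * c_ref + i * g
            o = sig(w.W_o @ hx + w.b_o)
            h_ref = o * np.tanh(c_ref)
            np.testing.assert_allclose(h, h_ref, atol=1e-10)
            np.testing.assert_allclose(c, c_ref, atol=1e-10)

    def test_hidden_state_is_bounded(self, rng):
        w = random_cell(rng, scale=3.0)
        h, c = np.zeros(3), np.zeros(3)
        for _ in range(50):
            h, c = lstm_cell_step(rng.normal(size=2) * 5, h, c, w)
            assert np.all(np.abs(h) < 1.0)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            lstm_cell_step(np.ones(4), np.zeros(3), np.zeros(3), random_cell(rng))


class TestFusedWeights:
    def test_fuse_split_round_trip(self, rng):
        w = random_cell(rng)
        back = split_gate_weights(fuse_gate_weights(w))
        for name in ("W_f", "W_i", "W_C", "W_o", "b_f", "b_i", "b_C", "b_o"):
            np.testing.assert_array_equal(getattr(w, name), getattr(back, name))

    def test_zero_weights_fuse_to_zero(self):
        fused = fuse_gate_weights(zero_cell())
        assert not fused.W.any() and not fused.b.any()

    def test_fused_and_separate_paths_agree(self, rng):
        w = random_cell(rng)
        fused = fuse_gate_weights(w)
        h, c = np.zeros(3), np.zeros(3)
        hf, cf = np.zeros(3), np.zeros(3)
        for _ in range(6):
            x = rng.normal(size=2)
            h, c = lstm_cell_step(x, h, c, w)
            hf, cf = lstm_cell_step_fused(x, hf, cf, fused)
            np.testing.assert_allclose(h, hf, atol=1e-12)
            np.testing.assert_allclose(c, cf, atol=1e-12)

    def test_sequence_layer_agrees_with_cell_step(self, rng):
        """The batched training-path LSTM reproduces the single-step cell."""
        hidden, feats, steps = 4, 3, 6
        w = random_cell(rng, hidden=hidden, inputs=feats)
        fused = fuse_gate_weights(w)
        # training layer uses the row-vector layout: W rows = [Wh; Wx],
        # gate blocks [f, i, C', o] along columns
        W_row = np.zeros((hidden + feats, 4 * hidden))
        for gi, (Wg,) in enumerate([(w.W_f,), (w.W_i,), (w.W_C,), (w.W_o,)]):
            W_row[:hidden, gi * hidden : (gi + 1) * hidden] = Wg[:, :hidden].T
            W_row[hidden:, gi * hidden : (gi + 1) * hidden] = Wg[:, hidden:].T
        b_row = fused.b
        x = rng.normal(size=(2, steps, feats))
        seq = lstm_sequence(Tensor(x), Tensor(W_row), Tensor(b_row), hidden).data
        for bi in range(2):
            h, c = np.zeros(hidden), np.zeros(hidden)
            for t in range(steps):
                h, c = lstm_cell_step(x[bi, t], h, c, w)
                np.testing.assert_allclose(seq[bi, t], h, atol=1e-12)


class TestConv1d:
    def test_identity_kernel(self, rng):
        x = rng.normal(size=(2, 7, 1))
        kernel = np.array([[[0.0]], [[1.0]], [[0.0]]])
        out = conv1d_extract(Tensor(x), Tensor(kernel), activation="identity").data
        np.testing.assert_allclose(out, x, atol=1e-15)

    def test_preserves_sequence_length(self, rng):
        x = rng.normal(size=(3, 11, 4))
        kernel = rng.normal(size=(3, 4, 6))
        out = conv1d_extract(Tensor(x), Tensor(kernel)).data
        assert out.shape == (3, 11, 6)

    def test_averaging_kernel_on_ramp(self):
        """(1/3,1/3,1/3) on 1..5: interior entries are centered means; the
        ends see one zero-padded neighbor."""
        ramp = np.arange(1.0, 6.0).reshape(1, 5, 1)
        kernel = np.full((3, 1, 1), 1.0 / 3.0)
        out = conv1d_extract(Tensor(ramp), Tensor(kernel), activation="identity").data
        expected = np.array([(0 + 1 + 2), (1 + 2 + 3), (2 + 3 + 4),
                             (3 + 4 + 5), (4 + 5 + 0)]) / 3.0
        np.testing.assert_allclose(out.ravel(), expected, atol=1e-12)

    def test_kernel_5_keeps_length(self, rng):
        x = rng.normal(size=(1, 8, 2))
        kernel = rng.normal(size=(5, 2, 3))
        assert conv1d_extract(Tensor(x), Tensor(kernel)).data.shape == (1, 8, 3)

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(ValueError):
            conv1d_extract(Tensor(rng.normal(size=(1, 5, 2))),
                           Tensor(rng.normal(size=(4, 2, 3))))


class TestPool1d:
    def test_constant_sequence_unchanged(self):
        x = np.full((2, 6, 3), 1.7)
        np.testing.assert_array_equal(pool1d(Tensor(x)).data, x)

    def test_hand_example(self):
        x = np.array([1.0, 3.0, 2.0]).reshape(1, 3, 1)
        out = pool1d(Tensor(x)).data.ravel()
        np.testing.assert_array_equal(out, [3.0, 3.0, 2.0])

    def test_length_preserved(self, rng):
        x = rng.normal(size=(2, 9, 4))
        assert pool1d(Tensor(x)).data.shape == x.shape


class TestScaledDotAttention:
    def test_single_key_returns_value(self, rng):
        q = rng.normal(size=(5, 3))
        k = rng.normal(size=(1, 3))
        v = rng.normal(size=(1, 4))
        out = scaled_dot_attention(Tensor(q), Tensor(k), Tensor(v)).data
        np.testing.assert_allclose(out, np.repeat(v, 5, axis=0), atol=1e-12)

    def test_zero_query_gives_column_means(self, rng):
        q = np.zeros((3, 4))
        k = rng.normal(size=(6, 4))
        v = rng.normal(size=(6, 2))
        out = scaled_dot_attention(Tensor(q), Tensor(k), Tensor(v)).data
        np.testing.assert_allclose(out, np.tile(v.mean(axis=0), (3, 1)), atol=1e-12)

    def test_hand_computed_two_by_two(self):
        """d = 1: scores = q k / 1, softmax by hand, mixture by hand."""
        q = np.array([[1.0], [2.0]])
        k = np.array([[0.5], [-0.5]])
        v = np.array([[10.0], [20.0]])
        s = q @ k.T  # [[0.5,-0.5],[1,-1]]
        w0 = np.exp(0.5) / (np.exp(0.5) + np.exp(-0.5))
        w1 = np.exp(1.0) / (np.exp(1.0) + np.exp(-1.0))
        expected = np.array([[w0 * 10 + (1 - w0) * 20], [w1 * 10 + (1 - w1) * 20]])
        out = scaled_dot_attention(Tensor(q), Tensor(k), Tensor(v)).data
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_attention_rows_sum_to_one(self, rng):
        from yubadry.nn.autodiff import softmax

        q = rng.normal(size=(4, 8, 5))
        k = rng.normal(size=(4, 8, 5))
        weights = softmax(Tensor(q) @ Tensor(k).swapaxes(-1, -2) * (1 / np.sqrt(5)),
                          axis=-1).data
        np.testing.assert_allclose(weights.sum(axis=-1), 1.0, atol=1e-9)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            scaled_dot_attention(Tensor(rng.normal(size=(2, 3))),
                                 Tensor(rng.normal(size=(2, 4))),
                                 Tensor(rng.normal(size=(2, 2))))


def make_attention(rng, dm, heads, d, identity=False):
    if identity:
        assert heads == 1 and d == dm
        eye = lambda: Tensor(np.eye(dm))
        return AttentionWeights(w_q=[eye()], w_k=[eye()], w_v=[eye()],
                                w_o=Tensor(np.eye(dm)))
    t = lambda s: Tensor(rng.normal(size=s) * 0.4)
    return AttentionWeights(
        w_q=[t((dm, d)) for _ in range(heads)],
        w_k=[t((dm, d)) for _ in range(heads)],
        w_v=[t((dm, d)) for _ in range(heads)],
        w_o=t((heads * d, dm)),
    )


class TestMultiheadAttention:
    def test_single_identity_head_reduces_to_plain_attention(self, rng):
        x = rng.normal(size=(2, 5, 4))
        w = make_attention(rng, 4, 1, 4, identity=True)
        out = multihead_attention(Tensor(x), w).data
        ref = scaled_dot_attention(Tensor(x), Tensor(x), Tensor(x)).data
        np.testing.assert_allclose(out, ref, atol=1e-12)

    def test_output_shape(self, rng):
        x = rng.normal(size=(3, 7, 6))
        w = make_attention(rng, 6, 2, 3)
        assert multihead_attention(Tensor(x), w).data.shape == (3, 7, 6)

    def test_fused_matches_composed_two_heads(self, rng):
        """Compositional oracle: manual per-head attention, concat, project."""
        x = rng.normal(size=(2, 4, 6))
        w = make_attention(rng, 6, 2, 3)
        fused = multihead_attention(Tensor(x), w).data
        composed = multihead_attention_composed(Tensor(x), w).data
        np.testing.assert_allclose(fused, composed, atol=1e-12)
        manual_heads = []
        for i in range(2):
            q = x @ w.w_q[i].data
            k = x @ w.w_k[i].data
            v = x @ w.w_v[i].data
            manual_heads.append(
                scaled_dot_attention(Tensor(q), Tensor(k), Tensor(v)).data)
        manual = np.concatenate(manual_heads, axis=-1) @ w.w_o.data
        np.testing.assert_allclose(fused, manual, atol=1e-12)

    def test_head_list_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            AttentionWeights(w_q=[Tensor(np.eye(2))], w_k=[], w_v=[],
                             w_o=Tensor(np.eye(2)))
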