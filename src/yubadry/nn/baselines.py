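"""Baseline predictors the attention-augmented network is compared against:
linear regression (LR), degree-2 polynomial regression (PR), a one-hidden-
layer feed-forward network (ANN), and a plain LSTM without the convolutional
or attention blocks.

All baselines share the window-in / 3-vector-out contract of the main model
so they can be trained, evaluated and benchmarked interchangeably.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.preprocessing import PolynomialFeatures

from .autodiff import Tensor
from .layers import lstm_sequence
from .model import glorot_uniform

__all__ = [
    "LinearWindowRegressor",
    "PolynomialWindowRegressor",
    "MlpRegressor",
    "PlainLstm",
    "make_baseline",
]


def _lstsq_fit(X: np.ndarray, Y: np.ndarray, ridge: float = 1e-8) -> np.ndarray:
    """Least squares with intercept; falls back to a ridge solve when the
    design matrix is rank-deficient (with a warning)."""
    A = np.hstack([np.ones((X.shape[0], 1)), X])
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        warnings.warn(
            f"design matrix is rank-deficient ({rank} < {A.shape[1]}); "
            "using a ridge-regularized solve",
            stacklevel=3,
        )
        AtA = A.T @ A + ridge * np.eye(A.shape[1])
        return np.linalg.solve(AtA, A.T @ Y)
    coef, *_ = np.linalg.lstsq(A, Y, rcond=None)
    return coef


class LinearWindowRegressor:
    """Least-squares fit of the 3 targets on the flattened window."""

    name = "LR"

    def __init__(self) -> None:
        self.coef_: np.ndarray | None = None

    def fit(self, windows: np.ndarray, targets: np.ndarray) -> "LinearWindowRegressor":
        X = np.asarray(windows, float).reshape(len(windows), -1)
        self.coef_ = _lstsq_fit(X, np.asarray(targets, float))
        return self

    def predict(self, windows: np.ndarray) -> np.ndarray:
        X = np.asarray(windows, float).reshape(len(windows), -1)
        return np.hstack([np.ones((len(X), 1)), X]) @ self.coef_


class PolynomialWindowRegressor:
    """Least squares on the degree-2 expansion of the flattened window."""

    name = "PR"

    def __init__(self, degree: int = 2) -> None:
        self.expander = PolynomialFeatures(degree=degree, include_bias=False)
        self.coef_: np.ndarray | None = None

    def fit(self, windows: np.ndarray, targets: np.ndarray) -> "PolynomialWindowRegressor":
        X = self.expander.fit_transform(
            np.asarray(windows, float).reshape(len(windows), -1)
        )
        self.coef_ = _lstsq_fit(X, np.asarray(targets, float))
        return self

    def predict(self, windows: np.ndarray) -> np.ndarray:
        X = self.expander.transform(
            np.asarray(windows, float).reshape(len(windows), -1)
        )
        return np.hstack([np.ones((len(X), 1)), X]) @ self.coef_


class MlpRegressor:
    """One-hidden-layer network on the flattened window, trained like the
    main model (Adam on MSE)."""

    name = "ANN"

    def __init__(self, window: int, features: int, hidden: int = 64, seed: int = 0):
        self.window, self.features, self.hidden = window, features, hidden
        rng = np.random.default_rng(seed)
        n_in = window * features
        self.params = {
            "W1": Tensor(glorot_uniform(rng, (n_in, hidden)), requires_grad=True),
            "b1": Tensor(np.zeros(hidden), requires_grad=True),
            "W2": Tensor(glorot_uniform(rng, (hidden, 3)), requires_grad=True),
            "b2": Tensor(np.zeros(3), requires_grad=True),
        }

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def forward(self, x: Tensor) -> Tensor:
        x = Tensor._lift(x)
        flat = x.reshape(x.shape[0], self.window * self.features)
        p = self.params
        hidden = (flat @ p["W1"] + p["b1"]).relu()
        return hidden @ p["W2"] + p["b2"]

    def predict(self, windows: np.ndarray) -> np.ndarray:
        return self.forward(Tensor(np.asarray(windows, float))).data


class PlainLstm:
    """Single LSTM layer plus affine head; the ablation without CNN or MHA."""

    name = "LSTM"

    def __init__(self, features: int, hidden: int = 64, seed: int = 0):
        self.features, self.hidden = features, hidden
        rng = np.random.default_rng(seed)
        self.params = {
            "lstm.W": Tensor(glorot_uniform(rng, (features + hidden, 4 * hidden)),
                             requires_grad=True),
            "lstm.b": Tensor(np.zeros(4 * hidden), requires_grad=True),
            "head.W": Tensor(glorot_uniform(rng, (hidden, 3)), requires_grad=True),
            "head.b": Tensor(np.zeros(3), requires_grad=True),
        }

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def forward(self, x: Tensor) -> Tensor:
        x = Tensor._lift(x)
        p = self.params
        seq = lstm_sequence(x, p["lstm.W"], p["lstm.b"], self.hidden)
        return seq[:, -1, :] @ p["head.W"] + p["head.b"]

    def predict(self, windows: np.ndarray) -> np.ndarray:
        return self.forward(Tensor(np.asarray(windows, float))).data


def make_baseline(kind: str, *, window: int, features: int,
                  hidden: int = 64, seed: int = 0):
    """Factory for the Table-3-style comparison models."""
    if kind == "linear":
        return LinearWindowRegressor()
    if kind == "polynomial":
        return PolynomialWindowRegressor()
    if kind == "mlp":
        return MlpRegressor(window, features, hidden=hidden, seed=seed)
    if kind == "lstm_plain":
        return PlainLstm(features, hidden=hidden, seed=seed)
    raise ValueError(f"unknown baseline kind {kind!r}")
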