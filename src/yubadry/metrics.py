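"""Regression evaluation metrics: coefficient of determination R^2, root
mean square error, and mean absolute error.

R^2 = 1 - sum (y - yhat)^2 / sum (y - ybar)^2
RMSE = sqrt( sum (y - yhat)^2 / n )
MAE  = sum |y - yhat| / n
"""

from __future__ import annotations

import numpy as np

__all__ = ["r_squared", "rmse", "mae"]


def _pair(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    if y.size == 0:
        raise ValueError("empty input")
    return y, yhat


def r_squared(y, yhat) -> float:
    y, yhat = _pair(y, yhat)
    if y.size < 2:
        raise ValueError("R^2 needs at least two observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 is undefined for constant y")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def rmse(y, yhat) -> float:
    y, yhat = _pair(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def mae(y, yhat) -> float:
    y, yhat = _pair(y, yhat)
    return float(np.mean(np.abs(y - yhat)))
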