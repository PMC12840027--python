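"""Training protocol for the drying predictors.

Rolling-window extraction (stride 1, one-step-ahead target by default),
time-continuous 6:2:2 train/validation/test split, per-feature 0-1 min-max
normalization fitted on the training split only, full-batch Adam on the
mean squared error, and per-target evaluation (R^2 / RMSE / MAE) reported
in denormalized units.

Window rows carry (current moisture content d.b., drying time, DR, SR, dE)
and — in the default conditioning mode — the air-temperature setpoint of
the step each row's one-step-ahead counterpart experiences, which is the
handle the controller turns when it queries the model at candidate
temperatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import mae, r_squared, rmse
from .nn.autodiff import Tensor
from .twin import Trajectory

__all__ = [
    "NormalizationSpec",
    "WindowSample",
    "TrainConfig",
    "Dataset",
    "fit_normalizer",
    "make_windows",
    "split_622",
    "build_dataset",
    "train_model",
    "evaluate_predictions",
    "evaluate_model",
    "benchmark_table",
    "TARGET_CHANNELS",
]

#: order of the base window features
BASE_FEATURES = ("M_db", "t_min", "DR", "SR_pct", "dE")
#: indices (within the feature vector) whose statistics also normalize targets
TARGET_CHANNELS = (2, 3, 4)  # DR, SR_pct, dE
TARGETS = ("DR", "SR_pct", "dE")


@dataclass(frozen=True)
class NormalizationSpec:
    """Per-feature min/max fitted on the training split.

    apply: x -> (x - min) / (max - min); a constant feature maps to 0.5.
    Targets (next-stage DR, SR, dE) reuse the statistics of their input
    channels so that normalized predictions denormalize consistently.
    """

    names: tuple[str, ...]
    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.maxs < self.mins):
            raise ValueError("max must be >= min per feature")

    def _scale(self) -> np.ndarray:
        return self.maxs - self.mins

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        scale = self._scale()
        out = np.empty_like(x)
        const = scale == 0
        out[..., ~const] = (x[..., ~const] - self.mins[~const]) / scale[~const]
        out[..., const] = 0.5
        return out

    def invert(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        scale = self._scale()
        out = np.empty_like(x)
        const = scale == 0
        out[..., ~const] = x[..., ~const] * scale[~const] + self.mins[~const]
        out[..., const] = self.mins[const]
        return out

    def apply_targets(self, y: np.ndarray) -> np.ndarray:
        idx = list(TARGET_CHANNELS)
        sub = NormalizationSpec(tuple(self.names[i] for i in idx),
                                self.mins[idx], self.maxs[idx])
        return sub.apply(y)

    def invert_targets(self, y: np.ndarray) -> np.ndarray:
        idx = list(TARGET_CHANNELS)
        sub = NormalizationSpec(tuple(self.names[i] for i in idx),
                                self.mins[idx], self.maxs[idx])
        return sub.invert(y)

    def to_arrays(self) -> dict[str, np.ndarray]:
        return {"mins": self.mins, "maxs": self.maxs}

    @classmethod
    def from_arrays(cls, names, mins, maxs) -> "NormalizationSpec":
        return cls(tuple(names), np.asarray(mins, float), np.asarray(maxs, float))


def fit_normalizer(train_inputs: np.ndarray, names: tuple[str, ...]) -> NormalizationSpec:
    """Fit per-feature min/max on training-split window rows only."""
    x = np.asarray(train_inputs, dtype=float)
    if x.size == 0:
        raise ValueError("cannot fit a normalizer on an empty split")
    flat = x.reshape(-1, x.shape[-1])
    return NormalizationSpec(names=tuple(names),
                             mins=flat.min(axis=0), maxs=flat.max(axis=0))


@dataclass(frozen=True)
class WindowSample:
    """One rolling-window sample: raw (w x F) inputs, raw 3-vector target,
    and its origin (trajectory id, target time index)."""

    inputs: np.ndarray
    target: np.ndarray
    origin: tuple[str, int]


def make_windows(traj: Trajectory, w: int, horizon: int = 1,
                 conditioning: str = "append") -> list[WindowSample]:
    """Extract stride-1 rolling windows with a ``horizon``-step-ahead target.

    A trajectory of length n yields exactly ``n - w - horizon + 1`` samples.
    With ``conditioning='append'`` each row gains a sixth feature: the air
    temperature at that row's time + horizon (the "next-stage" setpoint).
    """
    if w < 1 or horizon < 1:
        raise ValueError("window and horizon must be >= 1")
    n = len(traj)
    if n < w + horizon:
        raise ValueError(
            f"trajectory of length {n} is too short for window {w} + horizon {horizon}"
        )
    cols = {name: traj.column(fld) for name, fld in
            zip(BASE_FEATURES, ("M_db", "t", "DR", "SR", "dE"))}
    feats = np.column_stack([cols[name] for name in BASE_FEATURES])
    if conditioning == "append":
        T_air = traj.column("T_air")
        t_next = np.empty(n)
        t_next[: n - horizon] = T_air[horizon:]
        t_next[n - horizon:] = T_air[-1]
        feats = np.column_stack([feats, t_next])
    elif conditioning != "none":
        raise ValueError(f"unknown conditioning mode {conditioning!r}")
    targets = feats[:, list(TARGET_CHANNELS)]
    traj_id = str(traj.metadata.get("scenario", "trajectory"))
    samples = []
    for s in range(n - w - horizon + 1):
        tgt_idx = s + w - 1 + horizon
        samples.append(
            WindowSample(inputs=feats[s : s + w].copy(),
                         target=targets[tgt_idx].copy(),
                         origin=(traj_id, tgt_idx))
        )
    return samples


def split_622(samples: list) -> tuple[list, list, list]:
    """Contiguous 6:2:2 split in time order: floor(0.6 n) / floor(0.2 n) /
    remainder, no shuffling."""
    n = len(samples)
    if n < 5:
        raise ValueError("need at least 5 samples for a 6:2:2 split")
    n_train = int(np.floor(0.6 * n))
    n_val = int(np.floor(0.2 * n))
    return (list(samples[:n_train]),
            list(samples[n_train : n_train + n_val]),
            list(samples[n_train + n_val :]))


@dataclass
class Dataset:
    """Normalized window arrays for the three splits plus the normalizer."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_val: np.ndarray
    y_val: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    normalizer: NormalizationSpec
    feature_names: tuple[str, ...]
    origins: dict = field(default_factory=dict)


def _stack(samples: list[WindowSample]) -> tuple[np.ndarray, np.ndarray]:
    if not samples:
        f = samples  # empty
        return np.empty((0, 0, 0)), np.empty((0, 3))
    return (np.stack([s.inputs for s in samples]),
            np.stack([s.target for s in samples]))


def build_dataset(trajectories: list[Trajectory], w: int = 10, horizon: int = 1,
                  conditioning: str = "append") -> Dataset:
    """Windows are extracted per trajectory (never crossing a trajectory
    boundary), concatenated in scenario order, and split 6:2:2
    time-continuously over the concatenated set; normalization statistics
    come from the training portion only.

    Scenario order therefore decides which runs the held-out splits come
    from: with :func:`yubadry.twin.default_scenarios` the training portion
    spans the envelope extremes and the varying-temperature runs, and the
    test portion holds out runs at interior temperatures.
    """
    names = BASE_FEATURES + (("T_next",) if conditioning == "append" else ())
    samples: list[WindowSample] = []
    origins: dict[str, int] = {}
    for traj in trajectories:
        traj_samples = make_windows(traj, w, horizon, conditioning)
        samples += traj_samples
        origins[str(traj.metadata.get("scenario", f"traj{len(origins)}"))] = len(traj_samples)
    train, val, test = split_622(samples)
    X_tr, y_tr = _stack(train)
    X_va, y_va = _stack(val)
    X_te, y_te = _stack(test)
    norm = fit_normalizer(X_tr, names)
    return Dataset(
        X_train=norm.apply(X_tr), y_train=norm.apply_targets(y_tr),
        X_val=norm.apply(X_va), y_val=norm.apply_targets(y_va),
        X_test=norm.apply(X_te), y_test=norm.apply_targets(y_te),
        normalizer=norm, feature_names=names, origins=origins,
    )


@dataclass
class TrainConfig:
    """Optimizer protocol: MSE loss, Adam, full-batch by default."""

    window: int = 10
    horizon: int = 1
    learning_rate: float = 0.01
    iterations: int = 5000
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    batch_size: int | None = None  # None = full batch
    seed: int = 0
    log_every: int = 0

    def __post_init__(self) -> None:
        if self.window < 1 or self.horizon < 1 or self.iterations < 1:
            raise ValueError("window, horizon and iterations must be >= 1")


def train_model(model, X: np.ndarray, y: np.ndarray, cfg: TrainConfig,
                log=None) -> list[float]:
    """Minimize MSE over the (normalized) targets with Adam.

    Returns the full loss trace (one entry per optimizer step, evaluated on
    the step's batch).  Deterministic given ``cfg.seed``.  Aborts with a
    diagnostic if the loss goes non-finite.
    """
    params = model.parameters()
    dtype = params[0].data.dtype if params else np.float64
    X = np.asarray(X, dtype=dtype)
    y = np.asarray(y, dtype=dtype)
    m = [np.zeros_like(p.data) for p in params]
    v = [np.zeros_like(p.data) for p in params]
    rng = np.random.default_rng(cfg.seed)
    history: list[float] = []
    for step in range(1, cfg.iterations + 1):
        if cfg.batch_size is None or cfg.batch_size >= len(X):
            xb, yb = X, y
        else:
            idx = rng.choice(len(X), size=cfg.batch_size, replace=False)
            xb, yb = X[idx], y[idx]
        for p in params:
            p.zero_grad()
        pred = model.forward(Tensor(xb))
        err = pred - Tensor(yb)
        loss = (err * err).mean(axis=None)
        loss_val = float(loss.data)
        if not np.isfinite(loss_val):
            raise RuntimeError(
                f"training diverged: non-finite loss at iteration {step}"
            )
        history.append(loss_val)
        loss.backward()
        lr_t = cfg.learning_rate * np.sqrt(1 - cfg.beta2**step) / (1 - cfg.beta1**step)
        for i, p in enumerate(params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            m[i] = cfg.beta1 * m[i] + (1 - cfg.beta1) * g
            v[i] = cfg.beta2 * v[i] + (1 - cfg.beta2) * g * g
            p.data -= lr_t * m[i] / (np.sqrt(v[i]) + cfg.eps)
        if log is not None and cfg.log_every and step % cfg.log_every == 0:
            log(step, loss_val)
    return history


# ------------------------------------------------------------------ reports
def evaluate_predictions(y_true_n: np.ndarray, y_pred_n: np.ndarray,
                         normalizer: NormalizationSpec) -> pd.DataFrame:
    """Per-target R^2 / RMSE / MAE in denormalized units."""
    y_true = normalizer.invert_targets(np.asarray(y_true_n, float))
    y_pred = normalizer.invert_targets(np.asarray(y_pred_n, float))
    rows = []
    for j, target in enumerate(TARGETS):
        rows.append({
            "target": target,
            "R2": r_squared(y_true[:, j], y_pred[:, j]),
            "RMSE": rmse(y_true[:, j], y_pred[:, j]),
            "MAE": mae(y_true[:, j], y_pred[:, j]),
        })
    return pd.DataFrame(rows)


def evaluate_model(model, X_n: np.ndarray, y_n: np.ndarray,
                   normalizer: NormalizationSpec) -> pd.DataFrame:
    return evaluate_predictions(y_n, model.predict(X_n), normalizer)


def benchmark_table(models: dict, datasets: dict[str, Dataset]) -> pd.DataFrame:
    """Model-comparison table: one row per model x scenario x target with
    test-split R^2 / RMSE / MAE (denormalized units)."""
    frames = []
    for scenario, ds in datasets.items():
        for name, model in models.items():
            rep = evaluate_model(model, ds.X_test, ds.y_test, ds.normalizer)
            rep.insert(0, "scenario", scenario)
            rep.insert(0, "model", name)
            frames.append(rep)
    return pd.concat(frames, ignore_index=True)
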