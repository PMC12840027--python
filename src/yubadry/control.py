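"""Real-time drying-temperature control.

Once per minute the controller asks the predictor what (DR, SR, dE) the
next stage would bring at every candidate temperature, scores the
candidates with a min-max-normalized weighted sum (drying rate and
yellowing are benefits, shrinkage is a cost), commands the best setpoint
through a discrete positional PID with anti-windup, and stops once the
wet-basis moisture reaches the endpoint.

The comprehensive score for candidate c is

    score(c) = w_DR * n(DR_c) + w_dE * n(dE_c) - w_SR * n(SR_c)

where n() min-max normalizes each prediction across the candidate set (a
constant column normalizes to 0.5).  Ties are broken toward the lowest
temperature (energy rationale).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .twin import TwinParams, TwinRng, Trajectory, arrhenius_rate, initial_state, step_twin
from .training import NormalizationSpec

__all__ = [
    "ControllerConfig",
    "PidState",
    "ControlDecision",
    "composite_score",
    "select_setpoint",
    "pid_step",
    "run_closed_loop",
    "NeuralPredictor",
    "OracleTwinPredictor",
    "decisions_to_frame",
]


@dataclass(frozen=True)
class ControllerConfig:
    candidate_temps: tuple[float, ...] = tuple(float(t) for t in range(50, 71))
    score_weights: tuple[float, float, float] = (0.4, 0.3, 0.3)  # (w_DR, w_dE, w_SR)
    decision_period: float = 1.0   # min
    endpoint_wb: float = 0.10
    pid_gains: tuple[float, float, float] = (2.0, 0.1, 0.5)  # Kp, Ki [1/min], Kd [min]
    output_limits: tuple[float, float] = (45.0, 75.0)        # deg C
    anti_windup: float = 10.0      # integral clamp, deg C
    warmup_temp: float = 60.0      # held before the first full window exists

    def __post_init__(self) -> None:
        if not self.candidate_temps:
            raise ValueError("need at least one candidate temperature")
        lo, hi = self.output_limits
        if any(t < lo or t > hi for t in self.candidate_temps):
            raise ValueError("candidate temperatures must lie within output_limits")
        if any(w < 0 for w in self.score_weights):
            raise ValueError("score weights must be non-negative")
        if abs(sum(self.score_weights) - 1.0) > 1e-9:
            raise ValueError("score weights must sum to 1")
        if self.decision_period <= 0:
            raise ValueError("decision_period must be positive")


@dataclass
class PidState:
    integral: float = 0.0
    prev_error: float | None = None


@dataclass(frozen=True)
class ControlDecision:
    t: float
    candidates: tuple[float, ...]
    predictions: np.ndarray   # (n_candidates, 3) denormalized (DR, SR, dE)
    scores: np.ndarray
    chosen: float


def _minmax(col: np.ndarray) -> np.ndarray:
    span = col.max() - col.min()
    if span == 0:
        return np.full_like(col, 0.5)
    return (col - col.min()) / span


def composite_score(predictions: np.ndarray,
                    weights: tuple[float, float, float]) -> np.ndarray:
    """Score each candidate from its predicted (DR, SR, dE).

    ``predictions`` has one row per candidate, columns (DR, SR, dE);
    ``weights`` is (w_DR, w_dE, w_SR).  Higher is better.
    """
    preds = np.asarray(predictions, dtype=float)
    if preds.ndim != 2 or preds.shape[1] != 3:
        raise ValueError("predictions must be (n_candidates, 3) as (DR, SR, dE)")
    if preds.shape[0] < 1:
        raise ValueError("empty candidate set")
    if not np.all(np.isfinite(preds)):
        raise ValueError("predictions must be finite")
    w_dr, w_de, w_sr = weights
    n_dr = _minmax(preds[:, 0])
    n_sr = _minmax(preds[:, 1])
    n_de = _minmax(preds[:, 2])
    return w_dr * n_dr + w_de * n_de - w_sr * n_sr


# --------------------------------------------------------------- predictors
class NeuralPredictor:
    """Wraps a trained network + normalizer for candidate-conditioned queries.

    The window's last row carries the next-stage temperature feature; one
    batched forward pass evaluates every candidate.
    """

    def __init__(self, model, normalizer: NormalizationSpec, window: int):
        self.model = model
        self.normalizer = normalizer
        self.window = window

    def predict_candidates(self, history: np.ndarray,
                           candidates: tuple[float, ...]) -> np.ndarray:
        """``history``: raw (w x 6) feature rows (T_next column included;
        its last entry is overwritten per candidate).  Returns denormalized
        (n_candidates, 3) predictions ordered (DR, SR, dE)."""
        hist = np.asarray(history, dtype=float)
        if hist.shape != (self.window, len(self.normalizer.names)):
            raise ValueError(
                f"history must be ({self.window}, {len(self.normalizer.names)}), "
                f"got {hist.shape}"
            )
        batch = np.repeat(hist[None, :, :], len(candidates), axis=0)
        batch[:, -1, -1] = candidates
        preds_n = self.model.predict(self.normalizer.apply(batch))
        return self.normalizer.invert_targets(preds_n)


class OracleTwinPredictor:
    """Physics-based one-step-ahead predictor used as a controller test
    double: it answers candidate queries straight from the twin equations
    instead of a learned model."""

    def __init__(self, params: TwinParams, window: int = 1):
        self.params = params
        self.window = window

    def predict_candidates(self, history: np.ndarray,
                           candidates: tuple[float, ...]) -> np.ndarray:
        p = self.params
        m, t, dr, sr, de = history[-1, :5]
        out = np.empty((len(candidates), 3))
        for i, T in enumerate(candidates):
            k = arrhenius_rate(T, p.k_ref, p.T_ref, p.Ea)
            m_next = m * np.exp(-k * p.dt)
            loss = m - m_next
            frac = min(1.0, p.sr_gain * loss**p.sr_shape) if loss > 0 else 0.0
            sr_next = sr + max(0.0, p.sr_max(T) - sr) * frac
            b = arrhenius_rate(T, p.b_ref, p.T_ref, p.Eb)
            de_next = p.dE_max + (de - p.dE_max) * np.exp(-b * p.dt)
            out[i] = (loss / p.dt, sr_next, max(de_next, de))
        return out


def select_setpoint(predictor, history: np.ndarray,
                    cfg: ControllerConfig, t: float = 0.0) -> ControlDecision:
    """Query the predictor at every candidate temperature, score, and pick
    the argmax (ties toward the lowest temperature)."""
    preds = predictor.predict_candidates(history, cfg.candidate_temps)
    scores = composite_score(preds, cfg.score_weights)
    temps = np.asarray(cfg.candidate_temps, dtype=float)
    tied = scores == scores.max()
    best = int(np.argmin(np.where(tied, temps, np.inf)))
    return ControlDecision(t=t, candidates=cfg.candidate_temps,
                           predictions=preds, scores=scores,
                           chosen=float(cfg.candidate_temps[best]))


def pid_step(setpoint: float, measured: float, gains: tuple[float, float, float],
             state: PidState, dt: float,
             output_limits: tuple[float, float] = (-np.inf, np.inf),
             anti_windup: float = np.inf) -> tuple[float, PidState]:
    """Discrete positional PID tracking a temperature setpoint.

    u = setpoint + Kp e + Ki * sum(e dt) + Kd * de/dt, clamped to
    ``output_limits``.  Anti-windup clamps the integral *correction*
    (Ki * accumulator) to ``+/- anti_windup`` deg C.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    kp, ki, kd = gains
    e = setpoint - measured
    integral = state.integral + e * dt
    i_term = ki * integral
    if abs(i_term) > anti_windup and ki > 0:
        integral = np.sign(integral) * anti_windup / ki
        i_term = ki * integral
    d_term = 0.0 if state.prev_error is None else kd * (e - state.prev_error) / dt
    u = setpoint + kp * e + i_term + d_term
    u = float(np.clip(u, *output_limits))
    return u, PidState(integral=integral, prev_error=e)


def _history_from_states(states, window: int) -> np.ndarray:
    """Raw (window x 6) feature rows from the last ``window`` twin states.

    The T_next column holds each row's successor air temperature; the last
    row's entry is a placeholder that candidate queries overwrite.
    """
    recent = states[-window:]
    rows = np.array([[s.M_db, s.t, s.DR, s.SR, s.dE] for s in recent])
    t_next = np.array([recent[i + 1].T_air for i in range(len(recent) - 1)]
                      + [recent[-1].T_air])
    return np.column_stack([rows, t_next])


def run_closed_loop(params: TwinParams, predictor, cfg: ControllerConfig,
                    seed: int | None = None, max_time: float = 2000.0,
                    noisy: bool = False) -> tuple[Trajectory, list[ControlDecision]]:
    """Alternate twin stepping and per-minute decisions until the endpoint.

    The first ``window`` minutes run at ``cfg.warmup_temp`` so the predictor
    has a full history window before the first decision.  Returns the full
    trajectory and one :class:`ControlDecision` per decision instant.
    """
    window = getattr(predictor, "window", 1)
    params = replace(params, endpoint_wb=cfg.endpoint_wb)
    rng = TwinRng(params.seed if seed is None else seed) if noisy else None
    state = initial_state(params, T_air0=cfg.warmup_temp)
    states = [state]
    decisions: list[ControlDecision] = []
    pid = PidState()
    setpoint = cfg.warmup_temp
    next_decision = window * params.dt
    endpoint = False
    while state.t + params.dt <= max_time:
        if len(states) > window and state.t + 1e-9 >= next_decision:
            decision = select_setpoint(predictor,
                                       _history_from_states(states, window),
                                       cfg, t=state.t)
            decisions.append(decision)
            setpoint = decision.chosen
            next_decision += cfg.decision_period
        command, pid = pid_step(setpoint, state.T_air, cfg.pid_gains, pid,
                                params.dt, cfg.output_limits, cfg.anti_windup)
        state = step_twin(state, command, params, rng=rng)
        states.append(state)
        if state.M_wb <= params.endpoint_wb:
            endpoint = True
            break
    traj = Trajectory(
        states=states,
        metadata={
            "scenario": "closed_loop",
            "profile": {"type": "controlled"},
            "mode": "noisy" if rng is not None else "noise-free",
            "seed": (params.seed if seed is None else seed) if rng is not None else None,
            "endpoint_reached": endpoint,
        },
    )
    return traj, decisions


def decisions_to_frame(decisions: list[ControlDecision]) -> pd.DataFrame:
    """Long-format decision log: one row per (decision instant, candidate)."""
    rows = []
    for d in decisions:
        for i, T in enumerate(d.candidates):
            rows.append({
                "t_min": d.t,
                "candidate_T": T,
                "pred_DR": d.predictions[i, 0],
                "pred_SR": d.predictions[i, 1],
                "pred_dE": d.predictions[i, 2],
                "score": d.scores[i],
                "chosen": int(T == d.chosen),
            })
    return pd.DataFrame(rows, columns=["t_min", "candidate_T", "pred_DR",
                                       "pred_SR", "pred_dE", "score", "chosen"])
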