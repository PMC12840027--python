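"""Hot-air-drying digital twin.

Replaces the physical rig (chamber, load cell, camera) with a lumped
first-order process model so the predictor and controller can be exercised
end to end at desk scale:

* the chamber air temperature relaxes to the commanded setpoint with time
  constant ``tau_chamber``; the sample temperature relaxes to the air
  temperature with ``tau_sample`` (this heating lag produces the
  characteristic rise-then-fall of the drying-rate curve);
* dry-basis moisture decays first-order toward zero equilibrium with an
  Arrhenius rate evaluated at the sample temperature;
* the shrinkage rate relaxes toward a concave-quadratic, temperature-
  dependent asymptote at a speed proportional to the instantaneous
  moisture loss (shrinkage follows water removal and never reverses);
* the total color difference relaxes toward ``dE_max`` at an Arrhenius
  browning rate (Maillard yellowing, never reverses).

Measurement noise applies to the observed mass/area/color channels only;
the latent physics stays noise-free so analytic oracles remain exact.  The
observed mass is the average of two consecutive detections, and the drying
rate is the finite difference of those averaged masses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .colorimetry import ColorLab, delta_e
from .kinetics import db_to_wb, shrinkage_rate, wb_to_db

R_GAS = 8.314462618  # J / (mol K)
_ABS_ZERO_C = -273.15

__all__ = [
    "TwinParams",
    "DryingState",
    "Trajectory",
    "TemperatureProfile",
    "arrhenius_rate",
    "step_twin",
    "simulate",
    "generate_dataset",
    "constant_profile",
    "step_profile",
    "triangle_profile",
    "default_scenarios",
]


def arrhenius_rate(T, k_ref: float, T_ref: float, Ea: float):
    """Rate constant at temperature ``T`` (deg C) from a reference rate.

    k(T) = k_ref * exp(-Ea/R * (1/T_K - 1/T_ref_K)); strictly increasing
    in T for Ea > 0 and identically k_ref for Ea = 0.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= _ABS_ZERO_C):
        raise ValueError("temperature below absolute zero")
    if T_ref <= _ABS_ZERO_C:
        raise ValueError("reference temperature below absolute zero")
    t_k = T - _ABS_ZERO_C
    t_ref_k = T_ref - _ABS_ZERO_C
    out = k_ref * np.exp(-Ea / R_GAS * (1.0 / t_k - 1.0 / t_ref_k))
    return out.item() if out.ndim == 0 else out


@dataclass(frozen=True)
class TwinParams:
    """Physical and measurement parameters of the synthetic drying rig.

    Defaults emulate the study conditions: initial moisture 56.64 % w.b.,
    endpoint 10 % w.b., 1-min sampling, 50-70 deg C envelope, asymptotic
    shrinkage peaking near 60 deg C and spanning roughly 12-19 %, and a
    total color difference on the order of 4.
    """

    k_ref: float = 0.008          # 1/min at T_ref
    T_ref: float = 60.0           # deg C
    Ea: float = 30_000.0          # J/mol, moisture-removal activation energy
    tau_sample: float = 15.0      # min, sample heating lag
    tau_chamber: float = 3.0      # min, chamber heating lag
    sr_max_curve: tuple[float, float, float] = (19.26, 0.0, -0.0752)
    #   asymptotic SR(%) = a + b*(T - T_ref) + c*(T - T_ref)^2, concave (c < 0)
    sr_shape: float = 1.0         # exponent on the instantaneous moisture loss
    sr_gain: float = 3.0          # relaxation per unit (g/g) moisture lost
    dE_max: float = 4.2           # asymptotic total color difference
    b_ref: float = 0.010          # 1/min, browning rate at T_ref
    Eb: float = 40_000.0          # J/mol, browning activation energy
    M0_wb: float = 0.5664         # initial wet-basis moisture (fraction)
    endpoint_wb: float = 0.10     # drying endpoint, wet basis (fraction)
    noise_sd_mass: float = 0.0    # g/g on the mass (dry-basis) detection
    noise_sd_area: float = 0.0    # pixels on the projected-area detection
    noise_sd_color: float = 0.0   # per Lab channel
    dt: float = 1.0               # min, sampling interval
    seed: int = 0
    T_ambient: float = 25.0       # deg C, initial sample temperature
    area0_px: float = 50_000.0    # fresh projected area, pixels
    color0: tuple[float, float, float] = (81.5, -2.6, 2.6)  # fresh L*, a*, b*

    def __post_init__(self) -> None:
        if self.k_ref <= 0:
            raise ValueError("k_ref must be positive")
        if self.Ea < 0 or self.Eb < 0:
            raise ValueError("activation energies must be non-negative")
        if self.tau_sample <= 0 or self.tau_chamber <= 0:
            raise ValueError("time constants must be positive")
        if not 0 < self.endpoint_wb < self.M0_wb < 1:
            raise ValueError("need 0 < endpoint_wb < M0_wb < 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if min(self.noise_sd_mass, self.noise_sd_area, self.noise_sd_color) < 0:
            raise ValueError("noise standard deviations must be non-negative")

    @property
    def M0_db(self) -> float:
        return wb_to_db(self.M0_wb)

    @property
    def endpoint_db(self) -> float:
        return wb_to_db(self.endpoint_wb)

    def sr_max(self, T: float) -> float:
        a, b, c = self.sr_max_curve
        x = T - self.T_ref
        return float(np.clip(a + b * x + c * x * x, 0.0, 100.0))

    def fresh_color(self) -> ColorLab:
        return ColorLab(*self.color0)


@dataclass(frozen=True)
class _Latent:
    """Noise-free internal state carried alongside the observed record."""

    M_db: float
    SR: float
    dE: float
    det_prev: float   # previous raw mass detection (dry-basis units)
    avg_prev: float   # previous two-detection average


@dataclass(frozen=True)
class DryingState:
    """One 1-min observation of the drying process."""

    t: float
    T_air: float
    T_sample: float
    M_db: float
    M_wb: float
    MR: float
    DR: float
    area_px: float
    SR: float
    L: float
    a: float
    b: float
    dE: float
    latent: _Latent | None = field(default=None, repr=False, compare=False)


@dataclass
class Trajectory:
    """Ordered drying states at constant cadence plus run metadata."""

    states: list[DryingState]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self):
        return iter(self.states)

    @property
    def final(self) -> DryingState:
        return self.states[-1]

    def column(self, name: str) -> np.ndarray:
        return np.array([getattr(s, name) for s in self.states], dtype=float)


class TemperatureProfile:
    """A named setpoint schedule: callable minutes -> deg C."""

    def __init__(self, name: str, fn: Callable[[float], float], spec: dict):
        self.name = name
        self._fn = fn
        self.spec = spec  # serializable description

    def __call__(self, t: float) -> float:
        return float(self._fn(t))


def constant_profile(T: float) -> TemperatureProfile:
    return TemperatureProfile(f"const_{T:g}C", lambda t: T,
                              {"type": "constant", "T": T})


def step_profile(T1: float, T2: float, t_switch: float) -> TemperatureProfile:
    return TemperatureProfile(
        f"step_{T1:g}to{T2:g}C_at{t_switch:g}",
        lambda t: T1 if t < t_switch else T2,
        {"type": "step", "T1": T1, "T2": T2, "t_switch": t_switch},
    )


def triangle_profile(lo: float, hi: float, period: float) -> TemperatureProfile:
    """Symmetric triangle wave between ``lo`` and ``hi`` starting at ``lo``."""

    def fn(t: float) -> float:
        phase = (t % period) / period
        frac = 2 * phase if phase < 0.5 else 2 * (1 - phase)
        return lo + (hi - lo) * frac

    return TemperatureProfile(
        f"triangle_{lo:g}to{hi:g}C_p{period:g}",
        fn,
        {"type": "triangle", "lo": lo, "hi": hi, "period": period},
    )


def default_scenarios() -> list[TemperatureProfile]:
    """The five constant-temperature runs of the experimental design plus two
    varying-temperature runs that exercise the 50-70 deg C envelope.

    The ordering is deliberate: under the time-continuous 6:2:2 split over
    the concatenated window set, the training portion covers the envelope
    extremes (50 and 70 deg C) and both varying-temperature runs, so the
    held-out windows come from interior temperatures the model never saw —
    the standard temperature-interpolation check for drying models.
    """
    return [
        constant_profile(50),
        constant_profile(70),
        step_profile(55, 70, 150),
        triangle_profile(50, 70, 240),
        constant_profile(55),
        constant_profile(65),
        constant_profile(60),
    ]


class TwinRng:
    """Independent per-channel noise substreams derived from one seed.

    Stream order: mass, area, color (documented and stable).
    """

    def __init__(self, seed: int):
        mass_ss, area_ss, color_ss = np.random.SeedSequence(seed).spawn(3)
        self.mass = np.random.default_rng(mass_ss)
        self.area = np.random.default_rng(area_ss)
        self.color = np.random.default_rng(color_ss)


def initial_state(params: TwinParams, T_air0: float) -> DryingState:
    """The fresh-sample state: MR = 1, SR = 0, dE = 0, sample at ambient."""
    m0 = params.M0_db
    c0 = params.fresh_color()
    return DryingState(
        t=0.0, T_air=T_air0, T_sample=params.T_ambient,
        M_db=m0, M_wb=params.M0_wb, MR=1.0, DR=0.0,
        area_px=params.area0_px, SR=0.0,
        L=c0.L, a=c0.a, b=c0.b, dE=0.0,
        latent=_Latent(M_db=m0, SR=0.0, dE=0.0, det_prev=m0, avg_prev=m0),
    )


def step_twin(state: DryingState, T_air_command: float, params: TwinParams,
              rng: TwinRng | None = None) -> DryingState:
    """Advance the twin by one sampling interval ``params.dt``.

    Latent physics is integrated with exact exponential updates (uncondi-
    tionally stable for the first-order laws used here); observations are
    then derived from the latent state, with Gaussian noise if ``rng`` is
    given.
    """
    if T_air_command <= _ABS_ZERO_C:
        raise ValueError("commanded temperature below absolute zero")
    p = params
    lat = state.latent
    if lat is None:  # state loaded from CSV: treat observations as latent
        lat = _Latent(M_db=state.M_db, SR=state.SR, dE=state.dE,
                      det_prev=state.M_db, avg_prev=state.M_db)
    dt = p.dt

    # (i) thermal lags, sequential exponential updates
    T_air = T_air_command + (state.T_air - T_air_command) * math.exp(-dt / p.tau_chamber)
    T_sample = T_air + (state.T_sample - T_air) * math.exp(-dt / p.tau_sample)

    # (ii) first-order moisture decay toward zero equilibrium
    k = arrhenius_rate(T_sample, p.k_ref, p.T_ref, p.Ea)
    M_new = lat.M_db * math.exp(-k * dt)
    loss = lat.M_db - M_new  # g/g removed this step, >= 0

    # (iii) shrinkage relaxes toward its temperature-dependent asymptote,
    # driven by moisture loss; clamped non-decreasing
    frac = min(1.0, p.sr_gain * loss**p.sr_shape) if loss > 0 else 0.0
    sr_target = p.sr_max(T_sample)
    SR_new = lat.SR + max(0.0, sr_target - lat.SR) * frac

    # (iv) browning: dE relaxes toward dE_max at the Arrhenius rate b(T)
    b_rate = arrhenius_rate(T_sample, p.b_ref, p.T_ref, p.Eb)
    dE_new = p.dE_max + (lat.dE - p.dE_max) * math.exp(-b_rate * dt)
    dE_new = max(dE_new, lat.dE)

    # (v) observations; noise on mass/area/color channels only
    det = M_new + (rng.mass.normal(0.0, p.noise_sd_mass) if rng and p.noise_sd_mass else 0.0)
    det = max(det, 0.0)
    avg = 0.5 * (det + lat.det_prev)   # average of two consecutive detections
    M_obs = max(avg, 0.0)

    area_latent = p.area0_px * (1.0 - SR_new / 100.0)
    area_obs = area_latent + (rng.area.normal(0.0, p.noise_sd_area) if rng and p.noise_sd_area else 0.0)
    area_obs = max(area_obs, 0.0)
    SR_obs = shrinkage_rate(p.area0_px, min(area_obs, p.area0_px))

    c0 = p.fresh_color()
    lab = np.array([c0.L, c0.a, c0.b + dE_new])  # yellowing moves b* only
    if rng and p.noise_sd_color:
        lab = lab + rng.color.normal(0.0, p.noise_sd_color, size=3)
    lab[0] = float(np.clip(lab[0], 0.0, 100.0))
    dE_obs = delta_e(c0, ColorLab(L=lab[0], a=lab[1], b=lab[2]))

    # (vi) drying rate per the two-point finite difference of averaged masses
    DR_obs = (lat.avg_prev - avg) / dt

    return DryingState(
        t=state.t + dt, T_air=T_air, T_sample=T_sample,
        M_db=M_obs, M_wb=db_to_wb(M_obs), MR=M_obs / p.M0_db, DR=DR_obs,
        area_px=area_obs, SR=SR_obs,
        L=lab[0], a=lab[1], b=lab[2], dE=dE_obs,
        latent=_Latent(M_db=M_new, SR=SR_new, dE=dE_new,
                       det_prev=det, avg_prev=avg),
    )


def simulate(T_profile, params: TwinParams, max_time: float = 2000.0,
             noisy: bool = False, seed: int | None = None) -> Trajectory:
    """Run the twin under a setpoint schedule until the moisture endpoint.

    ``T_profile`` is a :class:`TemperatureProfile`, any callable minutes ->
    deg C, or a constant.  Iteration stops when the latent wet-basis
    moisture reaches ``endpoint_wb`` or at ``max_time``; the metadata flag
    ``endpoint_reached`` records which.
    """
    if max_time <= 0:
        raise ValueError("max_time must be positive")
    if isinstance(T_profile, (int, float)):
        T_profile = constant_profile(float(T_profile))
    elif not isinstance(T_profile, TemperatureProfile):
        T_profile = TemperatureProfile("custom", T_profile, {"type": "custom"})
    rng = TwinRng(params.seed if seed is None else seed) if noisy else None

    state = initial_state(params, T_air0=T_profile(0.0))
    states = [state]
    endpoint = False
    while state.t + params.dt <= max_time:
        command = T_profile(state.t + params.dt)
        state = step_twin(state, command, params, rng=rng)
        states.append(state)
        if state.M_wb <= params.endpoint_wb:
            endpoint = True
            break
    return Trajectory(
        states=states,
        metadata={
            "scenario": T_profile.name,
            "profile": T_profile.spec,
            "mode": "noisy" if rng is not None else "noise-free",
            "seed": (params.seed if seed is None else seed) if rng is not None else None,
            "endpoint_reached": endpoint,
        },
    )


def generate_dataset(scenarios: Sequence[TemperatureProfile], params: TwinParams,
                     out_dir, noisy: bool = False,
                     max_time: float = 2000.0) -> list[Path]:
    """Simulate every scenario and write one trajectory CSV per scenario.

    Per-scenario noise seeds are derived deterministically from
    ``params.seed`` and the scenario index, so the same parameters always
    produce byte-identical files.
    """
    from .dataio import write_trajectory  # local import: avoid cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for idx, profile in enumerate(scenarios):
        seed = int(np.random.SeedSequence((params.seed, idx)).generate_state(1)[0] % (2**31))
        traj = simulate(profile, params, max_time=max_time, noisy=noisy, seed=seed)
        path = out_dir / f"{profile.name}.csv"
        write_trajectory(traj, path)
        paths.append(path)
    return paths
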