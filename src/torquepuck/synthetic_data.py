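"""Synthetic trajectories with the statistical structure of the experiments.

Three generators cover the observation types the inference layer consumes:

* single-bacterium channel crossings -- the deterministic down-up angular
  profile ridden by rotational diffusion (Euler-Maruyama) and additive
  measurement noise on both the angle and the tracked bacterium position;
* chamber-occupancy recordings -- stepwise rotation rates driven by
  stochastic entry events;
* passive angle traces -- the thermal null model used to measure D_Theta.

All randomness flows through ``numpy.random.default_rng`` (PCG64), so a seed
fixes every trace bit-for-bit across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd

from .puck_model import ChamberLayout, PuckState, TorqueDipoleSpec, chamber_rate, crossing_profile

__all__ = [
    "AngleSeries",
    "CrossingTrajectory",
    "NoiseModel",
    "OccupancyTimeline",
    "generate_crossing",
    "generate_occupancy_series",
    "generate_passive",
]


@dataclass(frozen=True)
class NoiseModel:
    """Noise settings for synthetic trajectories.

    ``diffusivity`` is the physical rotational diffusivity of the puck
    (rad^2/s); the measurement standard deviations are detector-level and
    additive (not printed in the experiments; configurable defaults).
    """

    diffusivity: float = 6.0e-5
    angle_measurement_sd: float = 0.01
    position_measurement_sd: float = 0.2

    def __post_init__(self):
        if min(self.diffusivity, self.angle_measurement_sd,
               self.position_measurement_sd) < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass
class AngleSeries:
    """A plain (t, Theta) recording; angles unwrapped (cumulative)."""

    times: np.ndarray
    theta: np.ndarray
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.times.shape != self.theta.shape:
            raise ValueError("times and theta must have matching shapes")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.times, "theta_rad": self.theta})


@dataclass
class CrossingTrajectory:
    """A single channel crossing: (t, X_B, Theta) plus full metadata."""

    times: np.ndarray
    x_b: np.ndarray
    theta: np.ndarray
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.x_b = np.asarray(self.x_b, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if not (self.times.shape == self.x_b.shape == self.theta.shape):
            raise ValueError("times, x_b and theta must have matching shapes")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.times, "xb_um": self.x_b, "theta_rad": self.theta}
        )


@dataclass
class OccupancyTimeline:
    """Chamber entry/exit events: (time, chamber index, 'enter'|'exit', l_B)."""

    events: list[tuple[float, int, str, float]] = dc_field(default_factory=list)

    def occupancy_at(self, t: float) -> list[float]:
        occ: dict[int, float] = {}
        for time, chamber, kind, lb in self.events:
            if time > t:
                break
            if kind == "enter":
                occ[chamber] = lb
            else:
                occ.pop(chamber, None)
        return list(occ.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.events, columns=["t_s", "chamber", "event", "body_length_um"]
        )


def generate_crossing(
    bact: TorqueDipoleSpec,
    puck: PuckState,
    half_width: float,
    lam: float,
    noise: NoiseModel | None = None,
    dt: float = 0.1,
    seed=None,
    reversal_convention: str = "observed",
) -> CrossingTrajectory:
    """Simulate one noisy channel crossing.

    The mean angle follows the analytic profile at the true bacterium
    position X_B = U_s t; rotational diffusion is integrated by
    Euler-Maruyama and measurement noise is added independently to the
    reported angle and position.  The trace spans the crossing up to the
    torque-free freeze point.
    """
    if noise is None:
        noise = NoiseModel()
    x_end = 2.0 * puck.radius + bact.dipole_length
    t_end = x_end / bact.swim_speed
    if dt <= 0 or dt > t_end / 10.0:
        raise ValueError(
            f"dt must be positive and well below the crossing time {t_end:.3g} s"
        )
    rng = np.random.default_rng(seed)
    n = int(np.floor(t_end / dt))
    times = dt * np.arange(n + 1)
    x_true = bact.swim_speed * times
    theta_mean = crossing_profile(
        bact, puck, half_width, lam, x_true, reversal_convention=reversal_convention
    )
    dw = np.sqrt(2.0 * noise.diffusivity * dt) * rng.standard_normal(n)
    diffusion = np.concatenate([[0.0], np.cumsum(dw)])
    theta = (
        theta_mean
        + diffusion
        + noise.angle_measurement_sd * rng.standard_normal(n + 1)
    )
    x_rep = x_true + noise.position_measurement_sd * rng.standard_normal(n + 1)
    meta = {
        "seed": seed,
        "dt_s": dt,
        "half_width_um": half_width,
        "lambda": lam,
        "reversal_convention": reversal_convention,
        "bacterium": {
            "motor_torque_pN_um": bact.motor_torque,
            "body_length_um": bact.body_length,
            "alpha": bact.dipole_ratio,
            "swim_speed_um_s": bact.swim_speed,
            "swim_direction": bact.swim_direction,
        },
        "puck": {
            "radius_um": puck.radius,
            "rotational_mobility": puck.rotational_mobility,
            "rotational_diffusivity": puck.rotational_diffusivity,
            "temperature_K": puck.temperature,
        },
        "noise": {
            "diffusivity_rad2_s": noise.diffusivity,
            "angle_measurement_sd_rad": noise.angle_measurement_sd,
            "position_measurement_sd_um": noise.position_measurement_sd,
        },
    }
    return CrossingTrajectory(times=times, x_b=x_rep, theta=theta, metadata=meta)


def generate_passive(
    diffusivity: float, duration: float, dt: float, seed=None
) -> AngleSeries:
    """Pure rotational diffusion (Wiener) trace -- the thermal null model."""
    if diffusivity < 0:
        raise ValueError("diffusivity must be non-negative")
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    dw = np.sqrt(2.0 * diffusivity * dt) * rng.standard_normal(n)
    theta = np.concatenate([[0.0], np.cumsum(dw)])
    times = dt * np.arange(n + 1)
    return AngleSeries(
        times=times,
        theta=theta,
        metadata={"seed": seed, "diffusivity_rad2_s": diffusivity, "dt_s": dt},
    )


def generate_occupancy_series(
    layout: ChamberLayout,
    bacteria_pool: Sequence[TorqueDipoleSpec],
    entry_rate: float,
    duration: float,
    seed=None,
    puck: PuckState | None = None,
    half_width: float = 1.0,
    lam: float = 0.195,
    closed_correction: float = 1.0,
    diffusivity: float | None = None,
    dt: float = 0.1,
    exit_rate: float = 0.0,
) -> tuple[OccupancyTimeline, AngleSeries]:
    """Chamber-filling events and the resulting stepwise angle trace.

    Bacteria from ``bacteria_pool`` enter free chambers as a Poisson process
    of rate ``entry_rate`` (and leave at ``exit_rate`` per occupant, zero by
    default: the chambers are too narrow to reverse in).  Between events the
    mean angle advances at the additive closed-chamber rate; rotational
    diffusion is superposed.
    """
    if entry_rate < 0 or exit_rate < 0:
        raise ValueError("rates must be non-negative")
    if puck is None:
        puck = PuckState(radius=10.0, rotational_diffusivity=6.0e-5)
    if diffusivity is None:
        diffusivity = puck.rotational_diffusivity
    rng = np.random.default_rng(seed)
    pool = list(bacteria_pool)
    n = int(round(duration / dt))
    times = dt * np.arange(n + 1)
    theta = np.zeros(n + 1)
    occupants: dict[int, TorqueDipoleSpec] = {}
    timeline = OccupancyTimeline()
    pool_i = 0
    for i in range(n):
        free = [c for c in range(layout.n_chambers) if c not in occupants]
        if free and pool and entry_rate > 0 and rng.random() < 1 - np.exp(-entry_rate * dt):
            chamber = free[int(rng.integers(len(free)))]
            bact = pool[pool_i % len(pool)]
            pool_i += 1
            occupants[chamber] = bact
            timeline.events.append((times[i], chamber, "enter", bact.body_length))
        if exit_rate > 0:
            for chamber in list(occupants):
                if rng.random() < 1 - np.exp(-exit_rate * dt):
                    bact = occupants.pop(chamber)
                    timeline.events.append(
                        (times[i], chamber, "exit", bact.body_length)
                    )
        omega = chamber_rate(
            layout, list(occupants.values()), puck, half_width, lam,
            closed_correction=closed_correction,
        )
        theta[i + 1] = (
            theta[i]
            + omega * dt
            + np.sqrt(2.0 * diffusivity * dt) * rng.standard_normal()
        )
    series = AngleSeries(
        times=times,
        theta=theta,
        metadata={"seed": seed, "entry_rate_per_s": entry_rate, "dt_s": dt},
    )
    return timeline, series
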