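"""Configuration, table I/O and reproducible pipeline envelopes.

CSV carries trajectory tables (columns suffixed with their units: _s, _um,
_rad), YAML carries configuration, JSON carries results.  Every pipeline
result is wrapped in a ``ResultEnvelope`` recording the config hash, seed
and package version, so any number in an output file can be regenerated
from (config, seed) alone.  Angles are stored unwrapped (cumulative), since
the discs turn through many radians over minutes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import importlib.resources
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bath_model import BathParams
from .channel_hydro import ChannelGeometry
from .puck_model import PuckState, TorqueDipoleSpec
from .synthetic_data import AngleSeries, CrossingTrajectory, NoiseModel

__all__ = [
    "ConfigError",
    "RunConfig",
    "ResultEnvelope",
    "load_config",
    "default_config",
    "read_trajectory",
    "write_trajectory",
    "run_pipeline",
]

_SECTIONS = {
    "channel": {
        "half_width_um", "truncation_factor", "panel_size_um",
        "viscosity_pN_s_per_um2", "dead_end_um",
    },
    "bacterium": {"motor_torque_pN_um", "body_length_um", "alpha", "swim_speed_um_s"},
    "puck": {
        "radius_um", "rotational_diffusivity_rad2_s", "rotational_mobility",
        "temperature_K",
    },
    "bath": {
        "concentration_per_ml", "curvature_radius_um", "body_length_um",
        "force_pN", "contact_time_s", "rectification_c", "handedness",
        "collision_rate_per_s_per_um",
    },
    "simulation": {"dt_s", "bath_dt_s", "duration_s", "noise"},
    "inference": {
        "lambda", "msad_max_lag_fraction", "reversal_bandwidth_um", "alpha_fit_mode",
    },
}


class ConfigError(ValueError):
    """The configuration violates the schema."""


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration with explicit units in all key names."""

    channel: dict = field(default_factory=dict)
    bacterium: dict = field(default_factory=dict)
    puck: dict = field(default_factory=dict)
    bath: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)
    inference: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        for section, allowed in _SECTIONS.items():
            data = getattr(self, section)
            if not isinstance(data, dict):
                raise ConfigError(f"section {section!r} must be a mapping")
            unknown = set(data) - allowed
            if unknown:
                raise ConfigError(
                    f"unknown keys in section {section!r}: {sorted(unknown)}"
                )
        for key in ("half_width_um", "truncation_factor", "panel_size_um",
                    "viscosity_pN_s_per_um2"):
            v = self.channel.get(key)
            if v is not None and v <= 0:
                raise ConfigError(f"channel.{key} must be positive")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    # --- constructors for the physical objects -------------------------------
    def geometry(self) -> ChannelGeometry:
        c = self.channel
        w = c.get("half_width_um", 1.0)
        return ChannelGeometry(
            half_width=w,
            truncation_length=c.get("truncation_factor", 20.0) * w,
            panel_size=c.get("panel_size_um", w / 4.0),
            dead_end=c.get("dead_end_um"),
            viscosity=c.get("viscosity_pN_s_per_um2", 1.0e-3),
        )

    def bacterium_spec(self) -> TorqueDipoleSpec:
        b = self.bacterium
        return TorqueDipoleSpec(
            motor_torque=b.get("motor_torque_pN_um", 2.0),
            body_length=b.get("body_length_um", 5.0),
            dipole_ratio=b.get("alpha", 1.5),
            swim_speed=b.get("swim_speed_um_s", 20.0),
        )

    def puck_state(self) -> PuckState:
        p = self.puck
        diff = p.get("rotational_diffusivity_rad2_s")
        mob = p.get("rotational_mobility")
        if diff is None and mob is None:
            diff = 6.0e-5  # measured thermal value, the packaged default
        return PuckState(
            radius=p.get("radius_um", 10.0),
            rotational_mobility=mob,
            rotational_diffusivity=diff,
            temperature=p.get("temperature_K", 298.15),
        )

    def bath_params(self) -> BathParams:
        b = self.bath
        return BathParams(
            concentration_per_ml=b.get("concentration_per_ml", 6.0e8),
            curvature_radius=b.get("curvature_radius_um", 50.0),
            body_length=b.get("body_length_um", 5.0),
            force=b.get("force_pN", 0.2),
            contact_time=b.get("contact_time_s", 0.25),
            rectification_c=b.get("rectification_c", 1.0),
            collision_rate_per_perimeter=b.get("collision_rate_per_s_per_um"),
            handedness=b.get("handedness", -1),
        )

    def noise_model(self) -> NoiseModel:
        n = self.simulation.get("noise", {}) or {}
        return NoiseModel(
            diffusivity=n.get("diffusivity_rad2_s", 6.0e-5),
            angle_measurement_sd=n.get("angle_measurement_sd_rad", 0.01),
            position_measurement_sd=n.get("position_measurement_sd_um", 0.2),
        )


def _from_mapping(data: dict) -> RunConfig:
    known = {"channel", "bacterium", "puck", "bath", "simulation", "inference", "seed"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
    return RunConfig(
        channel=data.get("channel", {}) or {},
        bacterium=data.get("bacterium", {}) or {},
        puck=data.get("puck", {}) or {},
        bath=data.get("bath", {}) or {},
        simulation=data.get("simulation", {}) or {},
        inference=data.get("inference", {}) or {},
        seed=int(data.get("seed", 0)),
    )


def load_config(path) -> RunConfig:
    """Read and schema-validate a YAML configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_mapping(data)


def default_config() -> RunConfig:
    """The packaged experiment-scale default configuration."""
    text = (
        importlib.resources.files("torquepuck")
        .joinpath("data/default_config.yaml")
        .read_text()
    )
    return _from_mapping(yaml.safe_load(text))


_REQUIRED_ANY = ("t_s", "theta_rad")


def read_trajectory(path):
    """Read a trajectory CSV into a typed series.

    Requires columns ``t_s`` and ``theta_rad`` (any order); with ``xb_um``
    present the result is a :class:`CrossingTrajectory`, otherwise an
    :class:`AngleSeries`.  Missing columns, NaNs and non-monotone time raise
    descriptive errors.  A JSON metadata sidecar (same stem, ``.json``) is
    loaded when present.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _REQUIRED_ANY if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required columns {missing}")
    cols = ["t_s", "theta_rad"] + (["xb_um"] if "xb_um" in df.columns else [])
    if df[cols].isna().any().any():
        raise ValueError(f"{path.name}: NaN values in {cols}")
    t = df["t_s"].to_numpy(dtype=float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ValueError(f"{path.name}: time column must be strictly increasing")
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if "xb_um" in df.columns:
        return CrossingTrajectory(
            times=t,
            x_b=df["xb_um"].to_numpy(dtype=float),
            theta=df["theta_rad"].to_numpy(dtype=float),
            metadata=meta,
        )
    return AngleSeries(times=t, theta=df["theta_rad"].to_numpy(dtype=float), metadata=meta)


def write_trajectory(obj, path, sidecar: bool = True) -> None:
    """Write a trajectory/series to CSV (+ JSON metadata sidecar)."""
    path = Path(path)
    obj.to_frame().to_csv(path, index=False)
    if sidecar and obj.metadata:
        path.with_suffix(".json").write_text(
            json.dumps(obj.metadata, indent=2, default=_json_default)
        )


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


@dataclass
class ResultEnvelope:
    """A result payload plus the provenance needed to regenerate it."""

    payload: dict
    config_hash: str
    seed: int
    command: str
    version: str = __version__
    timestamp: float = field(default_factory=_time.time)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=_json_default)

    @classmethod
    def from_json(cls, text: str) -> "ResultEnvelope":
        return cls(**json.loads(text))


def run_pipeline(config: RunConfig, command: str, seed: int | None = None,
                 **kwargs) -> ResultEnvelope:
    """Execute one named pipeline step deterministically from (config, seed).

    Commands: ``lambda``, ``profile``, ``simulate-crossing``,
    ``simulate-bath``, ``simulate-chamber``, ``estimate-rate``,
    ``estimate-diffusivity``.  Stochastic steps consume the seed; the
    deterministic ones ignore it (so their payloads are seed-independent).
    """
    from . import bath_model, channel_hydro, inference, puck_model, synthetic_data

    if seed is None:
        seed = config.seed
    sim = config.simulation
    if command == "lambda":
        geo = config.geometry()
        levels = kwargs.get("refinement_levels")
        res = channel_hydro.compute_lambda(geo, refinement_levels=levels)
        payload = {
            "lambda": res.value,
            "uncertainty": res.uncertainty,
            "per_level": {f"{h:.6g}": v for h, v in res.per_level.items()},
        }
    elif command == "profile":
        lam = _require_lambda(config)
        bact, puck = config.bacterium_spec(), config.puck_state()
        w = config.channel.get("half_width_um", 1.0)
        xb = np.linspace(0.0, 2 * puck.radius + bact.dipole_length, 401)
        dth = puck_model.crossing_profile(bact, puck, w, lam, xb)
        xs, depth = puck_model.reversal_point(bact, puck, w, lam)
        payload = {
            "xb_um": xb,
            "dtheta_rad": dth,
            "regime": np.where(
                xb <= xs, "dipole", np.where(xb <= xs + bact.dipole_length,
                                             "single-rotlet", "frozen")
            ).tolist(),
            "reversal_xb_um": xs,
            "dtheta_max_rad": depth,
        }
    elif command == "simulate-crossing":
        lam = _require_lambda(config)
        traj = synthetic_data.generate_crossing(
            config.bacterium_spec(), config.puck_state(),
            config.channel.get("half_width_um", 1.0), lam,
            noise=config.noise_model(), dt=sim.get("dt_s", 0.1), seed=seed,
        )
        payload = {
            "t_s": traj.times, "xb_um": traj.x_b, "theta_rad": traj.theta,
            "metadata": traj.metadata,
        }
    elif command == "simulate-bath":
        radius = kwargs.get("radius", config.puck.get("radius_um", 10.0))
        times, theta = bath_model.simulate_bath(
            config.bath_params(), radius,
            duration=sim.get("duration_s", 600.0),
            dt=sim.get("bath_dt_s", 0.02), seed=seed,
        )
        payload = {"t_s": times, "theta_rad": theta, "radius_um": radius}
    elif command == "simulate-chamber":
        lam = _require_lambda(config)
        layout = puck_model.ChamberLayout()
        bact = config.bacterium_spec()
        timeline, series = synthetic_data.generate_occupancy_series(
            layout, [bact], entry_rate=kwargs.get("entry_rate", 0.02),
            duration=sim.get("duration_s", 600.0), seed=seed,
            puck=config.puck_state(),
            half_width=config.channel.get("half_width_um", 1.0), lam=lam,
            dt=sim.get("dt_s", 0.1),
        )
        payload = {
            "t_s": series.times, "theta_rad": series.theta,
            "events": timeline.events,
        }
    elif command == "estimate-rate":
        series = kwargs["series"]
        est = inference.estimate_rate(series)
        payload = {"omega_rad_s": est.omega, "stderr": est.stderr}
    elif command == "estimate-diffusivity":
        series = kwargs["series"]
        est = inference.estimate_diffusivity(series)
        payload = {
            "diffusivity_rad2_s": est.diffusivity, "stderr": est.stderr,
            "diffusive": est.diffusive,
        }
    else:
        raise ValueError(f"unknown pipeline command {command!r}")
    return ResultEnvelope(
        payload=payload, config_hash=config.config_hash(), seed=seed, command=command
    )


def _require_lambda(config: RunConfig) -> float:
    lam = config.inference.get("lambda")
    if lam is None:
        raise ConfigError(
            "inference.lambda is unset; run the `lambda` command first or "
            "supply a value"
        )
    return float(lam)
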