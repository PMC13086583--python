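"""Collision rectification of plain discs in a chiral bacterial bath.

Above a no-slip floor, swimming E. coli trace clockwise circles of curvature
radius R_c ~ 50 um.  Collisions of these curved trajectories with the rim of
a sedimented disc are therefore slightly asymmetric: each contact transfers a
tangential impulse whose rectified fraction scales as l_B / R_c, the ratio of
the cell length to the trajectory curvature radius.  Summed over the
collision flux on the perimeter this yields a mean clockwise torque

    Gamma_bar = chi * c * F * (l_B / R_c) * (nu * 2 pi R) * R * tau_c,

with nu the collision rate per unit perimeter, F the per-collision force
scale, tau_c the contact time, c an order-unity rectification constant and
chi = -1 for clockwise-circling swimmers.  With the thin-disc mobility
scaling M_Theta ~ R^-3 the steady rate obeys omega = M Gamma_bar ~ 1/R and
the thermal diffusivity D_Theta = k_B T M ~ R^-3 -- the two power laws
measured for plain pucks.

``simulate_bath`` is the stochastic counterpart: Poisson collision events
carrying the rectified mean impulse plus a zero-mean unrectified component,
on top of thermal rotational diffusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import K_B, ROOM_TEMPERATURE

__all__ = [
    "BathParams",
    "DiscMobilityModel",
    "mean_rectified_torque",
    "predicted_rate",
    "simulate_bath",
]


@dataclass(frozen=True)
class BathParams:
    """Bulk parameters of the chiral bacterial bath.

    ``collision_rate_per_perimeter`` defaults to the kinetic estimate
    rho_B * U_s * l_B (volume concentration times swim speed times capture
    length), in s^-1 um^-1.  ``handedness`` is -1 for clockwise-circling
    swimmers (the no-slip-floor case), +1 for the mirror bath.
    """

    concentration_per_ml: float = 6.0e8
    curvature_radius: float = 50.0
    body_length: float = 5.0
    force: float = 0.2
    swim_speed: float = 20.0
    contact_time: float = 0.25
    rectification_c: float = 1.0
    collision_rate_per_perimeter: float | None = None
    handedness: int = -1

    def __post_init__(self):
        for name in (
            "concentration_per_ml", "curvature_radius", "body_length",
            "force", "swim_speed", "contact_time", "rectification_c",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.handedness not in (-1, +1):
            raise ValueError("handedness must be -1 or +1")
        if self.collision_rate_per_perimeter is None:
            rho_um3 = self.concentration_per_ml / 1.0e12  # cells per um^3
            object.__setattr__(
                self,
                "collision_rate_per_perimeter",
                rho_um3 * self.swim_speed * self.body_length,
            )


@dataclass(frozen=True)
class DiscMobilityModel:
    """Rigid-disc rotational mobility scaling M(R) = M0 (R/R0)^-3."""

    reference_radius: float = 10.0
    reference_mobility: float = 6.0e-5 / (K_B * ROOM_TEMPERATURE)
    exponent: float = -3.0

    def mobility(self, radius: float) -> float:
        if radius <= 0:
            raise ValueError("radius must be positive")
        return self.reference_mobility * (radius / self.reference_radius) ** self.exponent

    def diffusivity(self, radius: float, temperature: float = ROOM_TEMPERATURE) -> float:
        """Thermal D_Theta(R) = k_B T M(R), rad^2/s."""
        return K_B * temperature * self.mobility(radius)


def mean_rectified_torque(params: BathParams, radius: float) -> float:
    """Mean torque from rectified rim collisions, pN um (negative = clockwise).

    Scales as R^2 at fixed bath parameters (perimeter times lever arm) and
    vanishes for straight swimmers (R_c -> infinity).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    rectified = params.rectification_c * params.body_length / params.curvature_radius
    collision_rate = params.collision_rate_per_perimeter * 2.0 * np.pi * radius
    impulse = params.force * radius * params.contact_time
    return params.handedness * rectified * collision_rate * impulse


def predicted_rate(
    params: BathParams, radius: float, mobility: DiscMobilityModel
) -> float:
    """Closed-form mean rotation rate omega(R) = M(R) Gamma_bar(R) ~ 1/R, rad/s."""
    return mobility.mobility(radius) * mean_rectified_torque(params, radius)


def simulate_bath(
    params: BathParams,
    radius: float,
    duration: float,
    dt: float,
    seed,
    mobility: DiscMobilityModel | None = None,
    temperature: float = ROOM_TEMPERATURE,
    n_runs: int | None = None,
):
    """Stochastic angle trajectory of a plain disc in the chiral bath.

    Poisson collision events (rate nu * 2 pi R) each deliver an angular
    impulse M(R) F R tau_c times (c l_B / R_c * handedness + a zero-mean
    unit-variance unrectified part); thermal rotational diffusion with
    D = k_B T M(R) is superposed.  Reproducible for a given ``seed``
    (numpy PCG64 generator).

    Returns ``(times, theta)``; ``theta`` has shape (n_runs, n_steps + 1)
    when ``n_runs`` is given, else (n_steps + 1,).

    Raises ``ValueError`` when ``dt`` does not resolve the collision rate
    (lambda * dt > 0.5).
    """
    if mobility is None:
        mobility = DiscMobilityModel()
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    lam_rate = params.collision_rate_per_perimeter * 2.0 * np.pi * radius
    if lam_rate * dt > 0.5:
        raise ValueError(
            f"dt too coarse: collision rate {lam_rate:.3g}/s requires "
            f"dt <= {0.5 / lam_rate:.3g} s"
        )
    M = mobility.mobility(radius)
    D = K_B * temperature * M
    impulse_scale = M * params.force * radius * params.contact_time
    mean_impulse = (
        impulse_scale
        * params.rectification_c
        * params.body_length
        / params.curvature_radius
        * params.handedness
    )
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / dt))
    nr = n_runs if n_runs is not None else 1
    theta = np.zeros((nr, n_steps + 1))
    counts = rng.poisson(lam_rate * dt, size=(nr, n_steps))
    # sum of k unit-variance zero-mean impulses ~ N(0, k); add the rectified mean
    kicks = counts * mean_impulse + np.sqrt(counts) * impulse_scale * rng.standard_normal(
        (nr, n_steps)
    )
    thermal = np.sqrt(2.0 * D * dt) * rng.standard_normal((nr, n_steps))
    theta[:, 1:] = np.cumsum(kicks + thermal, axis=1)
    times = dt * np.arange(n_steps + 1)
    if n_runs is None:
        return times, theta[0]
    return times, theta
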