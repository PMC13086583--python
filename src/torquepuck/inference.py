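"""Estimators mirroring the experimental analysis chain.

Rotation rates come from ordinary least-squares fits of Theta(t); the
rotational diffusivity from the mean squared angular displacement (MSAD)
over overlapping windows, with a weighted through-origin fit whose slope is
2 D_Theta; the rotational mobility from the Stokes-Einstein relation
M_Theta = D_Theta / k_B T.  Channel crossings are re-parameterized by the
bacterium position X_B (which collapses different swim speeds), the
reversal of the down-up shape is located on the collapsed curve, and the
dipole-length ratio alpha is fitted from the pre-reversal linear branch,
whose slope is -Lambda (alpha l_B / W)(M_Theta / U_s) Gamma_M.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .constants import K_B
from .synthetic_data import AngleSeries, CrossingTrajectory

__all__ = [
    "RateEstimate",
    "DiffusivityEstimate",
    "AlphaFit",
    "estimate_rate",
    "estimate_diffusivity",
    "mobility_from_diffusivity",
    "collapse_crossings",
    "detect_reversal",
    "fit_alpha",
    "fit_length_collapse",
]


@dataclass(frozen=True)
class RateEstimate:
    """OLS rotation rate omega with its standard error."""

    omega: float
    stderr: float
    window: tuple[float, float]


@dataclass(frozen=True)
class DiffusivityEstimate:
    """MSAD-based D_Theta; ``diffusive`` flags whether MSAD is actually linear."""

    diffusivity: float
    stderr: float
    lag_range: tuple[float, float]
    diffusive: bool


@dataclass(frozen=True)
class AlphaFit:
    """Fitted dipole-length ratio alpha with covariance and residual summary."""

    alpha: float
    stderr: float
    ci95: tuple[float, float]
    mode: str
    n_trajectories: int
    residual_rms: float

    def __post_init__(self):
        if not self.alpha > 0:
            raise ValueError("fitted alpha must be positive")


def _series_arrays(series) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(series, AngleSeries):
        return series.times, series.theta
    if isinstance(series, CrossingTrajectory):
        return series.times, series.theta
    t, th = series
    return np.asarray(t, dtype=float), np.asarray(th, dtype=float)


def estimate_rate(series) -> RateEstimate:
    """Average rotation rate from a linear fit of Theta(t).

    Invariant to additive angle offsets and to shifts of the time origin.
    """
    t, th = _series_arrays(series)
    if len(t) < 10:
        raise ValueError("need at least 10 samples for a rate estimate")
    if np.ptp(t) == 0:
        raise ValueError("degenerate time axis")
    (slope, _), cov = np.polyfit(t, th, 1, cov=True)
    return RateEstimate(
        omega=float(slope),
        stderr=float(np.sqrt(cov[0, 0])),
        window=(float(t[0]), float(t[-1])),
    )


def mean_squared_angular_displacement(
    theta: np.ndarray, dt: float, lags: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """MSAD over overlapping windows at integer lags; returns (msad, n_pairs)."""
    msad = np.empty(len(lags), dtype=float)
    npairs = np.empty(len(lags), dtype=int)
    for i, lag in enumerate(lags):
        d = theta[lag:] - theta[:-lag]
        msad[i] = np.mean(d * d)
        npairs[i] = len(d)
    return msad, npairs


def estimate_diffusivity(
    series, lag_range: tuple[float, float] | None = None, max_lags: int = 200
) -> DiffusivityEstimate:
    """Rotational diffusivity from the MSAD slope.

    MSAD(tau) is computed over overlapping windows for lags in ``lag_range``
    (default [dt, duration/4]) and fitted through the origin, weighting each
    lag by its number of window pairs; D_Theta = slope / 2.  A quadratic
    term is also fitted as a drift diagnostic: pure deterministic rotation
    gives MSAD = (omega tau)^2, and when the quadratic part dominates the
    estimate is flagged non-diffusive.
    """
    t, th = _series_arrays(series)
    if len(t) < 16:
        raise ValueError("series too short for MSAD estimation")
    dt = float(np.mean(np.diff(t)))
    duration = t[-1] - t[0]
    if lag_range is None:
        lag_range = (dt, duration / 4.0)
    lo, hi = lag_range
    if hi > duration / 2.0 + 1e-12:
        raise ValueError("lag range exceeds half the series duration")
    lag_lo = max(int(np.ceil(lo / dt)), 1)
    lag_hi = max(int(np.floor(hi / dt)), lag_lo)
    lags = np.unique(
        np.round(np.linspace(lag_lo, lag_hi, min(max_lags, lag_hi - lag_lo + 1)))
    ).astype(int)
    msad, npairs = mean_squared_angular_displacement(th, dt, lags)
    taus = lags * dt
    w = npairs.astype(float)
    # weighted through-origin linear fit: slope = sum(w tau msad) / sum(w tau^2)
    slope = np.sum(w * taus * msad) / np.sum(w * taus**2)
    resid = msad - slope * taus
    dof = max(len(taus) - 1, 1)
    var_slope = np.sum(w * resid**2) / dof / np.sum(w * taus**2)
    # drift diagnostic: linear + quadratic fit
    X = np.stack([taus, taus**2], axis=1)
    Wm = np.diag(w)
    beta, *_ = np.linalg.lstsq(np.sqrt(Wm) @ X, np.sqrt(w) * msad, rcond=None)
    quad_frac = abs(beta[1]) * taus[-1] / max(abs(beta[0]) + abs(beta[1]) * taus[-1], 1e-300)
    diffusive = quad_frac < 0.5
    return DiffusivityEstimate(
        diffusivity=float(max(slope, 0.0) / 2.0),
        stderr=float(np.sqrt(max(var_slope, 0.0)) / 2.0),
        lag_range=(float(taus[0]), float(taus[-1])),
        diffusive=bool(diffusive),
    )


def mobility_from_diffusivity(diffusivity: float, temperature: float) -> float:
    """Stokes-Einstein rotational mobility M_Theta = D_Theta / (k_B T)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return diffusivity / (K_B * temperature)


def collapse_crossings(
    trajectories: Sequence[CrossingTrajectory],
    grid: np.ndarray,
    normalize_by_length: bool = False,
) -> pd.DataFrame:
    """Collapse crossings onto a common X_B grid.

    Each trace is re-parameterized by its bacterium position and linearly
    interpolated to ``grid``; the table reports the pointwise mean and
    standard deviation (of DeltaTheta, or DeltaTheta / l_B when
    ``normalize_by_length``).  Raises for non-monotone X_B.
    """
    grid = np.asarray(grid, dtype=float)
    curves = []
    for traj in trajectories:
        x = traj.x_b
        if not np.all(np.diff(x) > 0):
            # measurement noise can break strict monotonicity; a sorted
            # re-indexing is not the same trace, so refuse clearly
            raise ValueError(
                "X_B must be strictly increasing along a single crossing "
                "(smooth or re-track the trajectory first)"
            )
        if grid[0] < x[0] - 1e-9 or grid[-1] > x[-1] + 1e-9:
            raise ValueError("trajectory does not cover the collapse grid")
        dtheta = traj.theta - traj.theta[0]
        y = np.interp(grid, x, dtheta)
        if normalize_by_length:
            y = y / traj.metadata["bacterium"]["body_length_um"]
        curves.append(y)
    arr = np.array(curves)
    return pd.DataFrame(
        {
            "xb_um": grid,
            "dtheta_mean": arr.mean(axis=0),
            "dtheta_sd": arr.std(axis=0, ddof=1) if len(arr) > 1 else np.zeros(len(grid)),
            "n": len(arr),
        }
    )


def detect_reversal(
    collapsed: pd.DataFrame, bandwidth: float = 1.0
) -> tuple[float, float]:
    """Locate the down-up reversal on a collapsed curve.

    The mean curve is smoothed with a Gaussian kernel (``bandwidth`` in um)
    and the interior minimum located (ties broken toward smaller X_B); the
    depth is |DeltaTheta| at the minimum.  A monotone curve (minimum on the
    boundary) raises with a diagnostic.
    """
    x = collapsed["xb_um"].to_numpy()
    y = collapsed["dtheta_mean"].to_numpy()
    dx = float(np.mean(np.diff(x)))
    sigma = bandwidth / dx
    ys = gaussian_filter1d(y, sigma, mode="nearest") if sigma > 0 else y
    i = int(np.argmin(ys))  # argmin takes the first (smallest-X) minimum
    if i == 0 or i == len(x) - 1:
        raise ValueError(
            "no interior minimum: curve is monotone over the grid "
            f"(argmin at index {i})"
        )
    return float(x[i]), float(abs(ys[i]))


def fit_alpha(
    trajectories: Sequence[CrossingTrajectory],
    known: dict,
    mode: str = "pooled",
) -> AlphaFit:
    """Fit the dipole-length ratio alpha from pre-reversal branches.

    ``known`` supplies {'lam', 'half_width', 'motor_torque', 'mobility',
    ...}; per-trace swim speed and body length default to the trajectory
    metadata.  The pre-reversal branch DeltaTheta = -Lambda (alpha l_B / W)
    (M/U_s) Gamma_M X_B is linear in alpha, so alpha is the through-origin
    regression coefficient of DeltaTheta on the known prefactor times X_B.
    ``mode='pooled'`` fits all points jointly; ``mode='per_trace'`` fits
    each crossing and combines with inverse-variance weights.
    """
    lam = known["lam"]
    W = known["half_width"]
    preds, obs, per_trace = [], [], []
    for traj in trajectories:
        meta_b = traj.metadata.get("bacterium", {})
        meta_p = traj.metadata.get("puck", {})
        gamma = known.get("motor_torque", meta_b.get("motor_torque_pN_um"))
        mobility = known.get("mobility", meta_p.get("rotational_mobility"))
        u_s = known.get("swim_speed", meta_b.get("swim_speed_um_s"))
        l_b = known.get("body_length", meta_b.get("body_length_um"))
        radius = known.get("radius", meta_p.get("radius_um"))
        if None in (gamma, mobility, u_s, l_b, radius):
            raise ValueError("missing model parameters for alpha fit")
        x_star = 2.0 * radius - l_b
        mask = (traj.x_b >= 0) & (traj.x_b <= x_star)
        if mask.sum() < 5:
            raise ValueError("insufficient pre-reversal data in a trajectory")
        x = traj.x_b[mask]
        y = traj.theta[mask] - traj.theta[0]
        p = -lam * l_b / W * mobility / u_s * gamma * x
        a_i = np.sum(p * y) / np.sum(p * p)
        per_trace.append((a_i, float(np.sum(p * p))))
        preds.append(p)
        obs.append(y)
    # rotational diffusion makes residuals strongly correlated within a trace,
    # so standard errors come from the between-trace scatter (cluster-robust),
    # not from the pointwise residuals
    a = np.array([v[0] for v in per_trace])
    w_tr = np.array([v[1] for v in per_trace])
    n_tr = len(a)
    if mode == "pooled":
        p = np.concatenate(preds)
        y = np.concatenate(obs)
        alpha = np.sum(p * y) / np.sum(p * p)  # == sum(w_tr a)/sum(w_tr)
        resid = y - alpha * p
        rms = float(np.sqrt(np.mean(resid**2)))
        if n_tr > 1:
            var = float(
                np.sum(w_tr**2 * (a - alpha) ** 2)
                / np.sum(w_tr) ** 2
                * n_tr / (n_tr - 1)
            )
        else:
            var = np.sum(resid**2) / max(len(p) - 1, 1) / np.sum(p * p)
    elif mode == "per_trace":
        alpha = float(np.mean(a))
        var = float(np.var(a, ddof=1) / n_tr) if n_tr > 1 else 0.0
        rms = float(np.std(a, ddof=1)) if n_tr > 1 else 0.0
    else:
        raise ValueError("mode must be 'pooled' or 'per_trace'")
    se = float(np.sqrt(var))
    return AlphaFit(
        alpha=float(alpha),
        stderr=se,
        ci95=(float(alpha - 1.96 * se), float(alpha + 1.96 * se)),
        mode=mode,
        n_trajectories=len(trajectories),
        residual_rms=rms,
    )


def fit_length_collapse(
    rates: Sequence[tuple[float, float]], weights: Sequence[float] | None = None
) -> dict:
    """Zero-intercept fit of rotation rate against total trapped body length.

    ``rates`` holds (omega, sum_i l_B^i) pairs.  Returns the through-origin
    weighted least-squares slope with its standard error and residuals.
    """
    arr = np.asarray(rates, dtype=float)
    if len(arr) < 3:
        raise ValueError("need at least 3 points")
    omega, total_len = arr[:, 0], arr[:, 1]
    w = np.ones(len(arr)) if weights is None else np.asarray(weights, dtype=float)
    slope = np.sum(w * total_len * omega) / np.sum(w * total_len**2)
    resid = omega - slope * total_len
    var = np.sum(w * resid**2) / max(len(arr) - 1, 1) / np.sum(w * total_len**2)
    return {
        "slope": float(slope),
        "stderr": float(np.sqrt(var)),
        "residuals": resid,
        "n": len(arr),
    }
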