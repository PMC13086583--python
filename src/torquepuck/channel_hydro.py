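"""Stokes flow of point torques (rotlets) confined in a no-slip square duct.

A swimming bacterium whose flagellar motor spins the cell body and flagellar
bundle in opposite senses acts on the surrounding fluid as a pair of equal and
opposite point torques aligned with its swimming axis.  Inside a tightly
confining square channel the flow driven by each rotlet shears the channel
walls; the resulting viscous traction on the *top* wall (the underside of the
microdisc, or "puck", into which the channel is cut) transmits a net vertical
torque to the disc.

This module solves the confined Stokes problem with a boundary-element method
(method of regularized Stokeslets: flat rectangular wall panels carrying
piecewise-constant force densities, collocation at panel centres), evaluates
the wall traction carried to the puck, and computes the dimensionless
torque-transmission constant Lambda defined by

    Gamma_1 = -Lambda * (x_1 - x_C) / W * Gamma_M

for a single axial rotlet of strength Gamma_M at axial position x_1 under a
puck centred at x_C, in a duct of half-width W.

Sign conventions
----------------
x runs along the channel axis, z is normal to the substrate; the bottom wall
z = -W is the fixed substrate and the top wall z = +W belongs to the puck.
Panel densities are the force per unit area the wall exerts *on the fluid*;
the traction the fluid exerts on the puck is the negative of the density.
Puck angles are positive anticlockwise about +z viewed from above, so
clockwise rotation means a negative torque.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.linalg

__all__ = [
    "GeometryError",
    "SolverError",
    "Rotlet",
    "ChannelGeometry",
    "ChannelFlowSolution",
    "WallTractionField",
    "LambdaResult",
    "free_space_rotlet_velocity",
    "solve_channel_flow",
    "top_wall_traction",
    "puck_torque_from_traction",
    "compute_lambda",
    "closed_chamber_solution",
    "closed_chamber_correction",
    "mirror_rotlet",
]

logger = logging.getLogger(__name__)

#: Wall identifiers used in panel bookkeeping.
WALL_TOP, WALL_BOTTOM, WALL_SIDE_POS, WALL_SIDE_NEG, WALL_END = 0, 1, 2, 3, 4

#: Refuse dense solves whose estimated condition number exceeds this.
MAX_CONDITION = 1e12


class GeometryError(ValueError):
    """A source or probe violates the channel geometry."""


class SolverError(RuntimeError):
    """The panel system could not be solved reliably."""


@dataclass(frozen=True)
class Rotlet:
    """A point torque in Stokes flow.

    Parameters
    ----------
    position : (3,) array-like, um
    torque : (3,) array-like, pN um
        May be zero only for null/test cases.
    """

    position: np.ndarray
    torque: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        tor = np.asarray(self.torque, dtype=float)
        if pos.shape != (3,) or tor.shape != (3,):
            raise ValueError("Rotlet position and torque must be 3-vectors")
        if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(tor))):
            raise ValueError("Rotlet position and torque must be finite")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "torque", tor)


@dataclass(frozen=True)
class ChannelGeometry:
    """Square duct of half-width W truncated to a finite axial length.

    The duct cross-section is |y| <= W, |z| <= W; the axial coordinate spans
    [-L/2, +L/2].  Axial screening in a duct is exponential, so a truncation
    of a few tens of W stands in for the infinite channel; ends are left open
    (panel-free) by default.

    Parameters
    ----------
    half_width : float, um
    truncation_length : float, um
        Defaults to 40 * half_width.
    panel_size : float, um
        Target edge length of the square wall panels; must satisfy
        h <= W / 4.
    dead_end : float or None, um
        Axial coordinate of a closed end wall (closed-chamber problems).
    viscosity : float, pN s um^-2
    """

    half_width: float
    truncation_length: float | None = None
    panel_size: float | None = None
    dead_end: float | None = None
    viscosity: float = 1.0e-3

    def __post_init__(self):
        W = self.half_width
        if not W > 0:
            raise GeometryError("half_width must be positive")
        L = self.truncation_length if self.truncation_length is not None else 40.0 * W
        h = self.panel_size if self.panel_size is not None else W / 4.0
        object.__setattr__(self, "truncation_length", float(L))
        object.__setattr__(self, "panel_size", float(h))
        if L < 10.0 * W:
            raise GeometryError("truncation_length must be at least 10 half-widths")
        if h > W / 4.0 + 1e-12 * W:
            raise GeometryError("panel_size must not exceed half_width / 4")
        if self.viscosity <= 0:
            raise GeometryError("viscosity must be positive")
        if self.dead_end is not None and not (-L / 2 <= self.dead_end <= L / 2):
            raise GeometryError("dead_end must lie within the truncation window")

    @property
    def axial_window(self) -> tuple[float, float]:
        return (-self.truncation_length / 2.0, self.truncation_length / 2.0)

    def contains(self, point: np.ndarray, margin: float = 0.0) -> bool:
        x, y, z = np.asarray(point, dtype=float)
        W = self.half_width
        lo, hi = self.axial_window
        return (lo + margin < x < hi - margin) and (abs(y) < W - margin) and (abs(z) < W - margin)


def free_space_rotlet_velocity(torque, source, field_point, viscosity):
    """Velocity of the unbounded rotlet: U = Gamma x (r - r1) / (8 pi mu |r - r1|^3).

    Parameters are in package units (pN um, um, pN s um^-2); the result is in
    um/s.  ``field_point`` may be a single 3-vector or an (N, 3) array.
    Raises ``GeometryError`` for a field point coincident with the source.
    """
    torque = np.asarray(torque, dtype=float)
    source = np.asarray(source, dtype=float)
    pts = np.atleast_2d(np.asarray(field_point, dtype=float))
    d = pts - source[None, :]
    r2 = np.einsum("ij,ij->i", d, d)
    if np.any(r2 == 0.0):
        raise GeometryError("field point coincides with the rotlet position")
    u = np.cross(np.broadcast_to(torque, d.shape), d) / (
        8.0 * np.pi * viscosity * r2[:, None] ** 1.5
    )
    return u[0] if np.asarray(field_point).ndim == 1 else u


def _build_panels(geometry: ChannelGeometry, end_wall: bool = False):
    """Flat panels on the four duct walls (optionally plus a dead-end wall).

    Returns centers (M, 3), areas (M,), wall ids (M,).
    """
    W = geometry.half_width
    L = geometry.truncation_length
    h = geometry.panel_size
    nx = max(int(round(L / h)), 1)
    nt = max(int(round(2.0 * W / h)), 1)
    hx = L / nx
    ht = 2.0 * W / nt
    xs = -L / 2.0 + hx * (np.arange(nx) + 0.5)
    ts = -W + ht * (np.arange(nt) + 0.5)
    X, T = np.meshgrid(xs, ts, indexing="ij")
    X, T = X.ravel(), T.ravel()
    ones = np.ones_like(X)
    blocks = [
        (np.stack([X, T, +W * ones], axis=1), WALL_TOP),
        (np.stack([X, T, -W * ones], axis=1), WALL_BOTTOM),
        (np.stack([X, +W * ones, T], axis=1), WALL_SIDE_POS),
        (np.stack([X, -W * ones, T], axis=1), WALL_SIDE_NEG),
    ]
    centers = [b[0] for b in blocks]
    ids = [np.full(len(b[0]), b[1]) for b in blocks]
    areas = [np.full(len(b[0]), hx * ht) for b in blocks]
    if end_wall:
        if geometry.dead_end is None:
            raise GeometryError("end_wall panels require a dead_end coordinate")
        Y, Z = np.meshgrid(ts, ts, indexing="ij")
        cw = np.stack(
            [np.full(Y.size, geometry.dead_end), Y.ravel(), Z.ravel()], axis=1
        )
        centers.append(cw)
        ids.append(np.full(len(cw), WALL_END))
        areas.append(np.full(len(cw), ht * ht))
    return np.concatenate(centers), np.concatenate(areas), np.concatenate(ids)


def _reg_stokeslet_apply_matrix(targets, sources, areas, eps, mu, block=512):
    """Dense matrix mapping stacked panel forces to velocities at targets.

    Uses the standard 3D regularized-Stokeslet kernel
    G_eps(r) = [(r^2 + 2 eps^2) I + r r] / (r^2 + eps^2)^{3/2},
    one-point quadrature per panel (constant density, centre collocation).
    Layout: interleaved components [x0, y0, z0, x1, ...].
    """
    M = len(targets)
    N = len(sources)
    # Fortran order lets LAPACK factor in place without a transposed copy
    A = np.empty((3 * M, 3 * N), order="F")
    pref_row = areas / (8.0 * np.pi * mu)
    for i0 in range(0, M, block):
        i1 = min(i0 + block, M)
        d = targets[i0:i1, None, :] - sources[None, :, :]
        r2 = np.einsum("ijk,ijk->ij", d, d)
        den = (r2 + eps * eps) ** 1.5
        iso = (r2 + 2.0 * eps * eps) / den * pref_row[None, :]
        aniso = pref_row[None, :] / den
        for a in range(3):
            for b in range(3):
                blk = d[:, :, a] * d[:, :, b] * aniso
                if a == b:
                    blk = blk + iso
                A[3 * i0 + a : 3 * i1 : 3, b::3] = blk
    return A


@dataclass
class ChannelFlowSolution:
    """Solved confined-rotlet flow: wall panel densities plus an evaluator.

    ``densities`` hold the force per unit area each wall panel exerts on the
    fluid; the velocity anywhere inside the duct is the free-space rotlet
    field of all sources plus the regularized single-layer contribution of
    the panels.
    """

    geometry: ChannelGeometry
    sources: tuple[Rotlet, ...]
    panel_centers: np.ndarray
    panel_areas: np.ndarray
    panel_wall_id: np.ndarray
    densities: np.ndarray
    regularization: float
    condition_estimate: float
    noslip_residual: float
    image_sources: tuple[Rotlet, ...] = field(default_factory=tuple)

    @property
    def all_sources(self) -> tuple[Rotlet, ...]:
        return self.sources + self.image_sources

    def velocity(self, points) -> np.ndarray:
        """Fluid velocity (um/s) at interior points; (N, 3) for (N, 3) input."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        u = np.zeros_like(pts)
        for r in self.all_sources:
            u += free_space_rotlet_velocity(
                r.torque, r.position, pts, self.geometry.viscosity
            )
        eps = self.regularization
        mu = self.geometry.viscosity
        pref = self.panel_areas / (8.0 * np.pi * mu)
        block = 2048
        for i0 in range(0, len(pts), block):
            i1 = min(i0 + block, len(pts))
            d = pts[i0:i1, None, :] - self.panel_centers[None, :, :]
            r2 = np.einsum("ijk,ijk->ij", d, d)
            den = (r2 + eps * eps) ** 1.5
            iso = (r2 + 2.0 * eps * eps) / den * pref[None, :]
            aniso = pref[None, :] / den
            df = np.einsum("ijk,jk->ij", d, self.densities)
            u[i0:i1] += iso @ self.densities + np.einsum(
                "ij,ijk->ik", aniso * df, d
            )
        return u[0] if np.asarray(points).ndim == 1 else u

    def velocity_scale(self) -> float:
        """Characteristic rotlet velocity |Gamma| / (8 pi mu W^2)."""
        g = max((np.linalg.norm(r.torque) for r in self.all_sources), default=0.0)
        return g / (8.0 * np.pi * self.geometry.viscosity * self.geometry.half_width**2)


def solve_channel_flow(
    geometry: ChannelGeometry,
    sources: Sequence[Rotlet],
    tol_noslip: float = 1e-3,
    _extra_sources: Sequence[Rotlet] = (),
    _end_wall: bool = False,
) -> ChannelFlowSolution:
    """Solve the no-slip boundary-integral system for rotlets in the duct.

    The no-slip condition is collocated at panel centres; the resulting dense
    system is solved by LU factorization with a reciprocal-condition check
    (refused above ~1e12).  The solution is linear in the source torques, so
    superposition over the source list holds by construction.
    """
    sources = tuple(sources)
    extra = tuple(_extra_sources)
    for r in sources:
        if not geometry.contains(r.position):
            raise GeometryError(
                f"rotlet at {r.position} lies on or outside the duct walls"
            )
    centers, areas, wall_id = _build_panels(geometry, end_wall=_end_wall)
    eps = geometry.panel_size / 2.0
    mu = geometry.viscosity
    A = _reg_stokeslet_apply_matrix(centers, centers, areas, eps, mu)
    rhs = np.zeros((len(centers), 3))
    for r in sources + extra:
        rhs -= free_space_rotlet_velocity(r.torque, r.position, centers, mu)
    # 1-norm accumulated in row blocks to avoid duplicating the dense matrix
    colsums = np.zeros(A.shape[1])
    for i0 in range(0, A.shape[0], 1024):
        colsums += np.abs(A[i0 : i0 + 1024]).sum(axis=0)
    anorm = colsums.max()
    lu, piv = scipy.linalg.lu_factor(A, overwrite_a=True, check_finite=False)
    rcond, _ = scipy.linalg.lapack.dgecon(lu, anorm)
    cond = 1.0 / max(rcond, np.finfo(float).tiny)
    logger.debug(
        "panel system: %d panels, condition estimate %.3e", len(centers), cond
    )
    if cond > MAX_CONDITION:
        raise SolverError(
            f"panel system ill-conditioned (condition estimate {cond:.3e})"
        )
    f = scipy.linalg.lu_solve((lu, piv), rhs.ravel(), check_finite=False).reshape(-1, 3)
    sol = ChannelFlowSolution(
        geometry=geometry,
        sources=sources,
        panel_centers=centers,
        panel_areas=areas,
        panel_wall_id=wall_id,
        densities=f,
        regularization=eps,
        condition_estimate=cond,
        noslip_residual=0.0,
        image_sources=extra,
    )
    scale = sol.velocity_scale()
    if scale > 0:
        resid = np.abs(sol.velocity(centers)).max() / scale
        sol.noslip_residual = float(resid)
        logger.debug("no-slip residual at collocation points: %.3e", resid)
        if resid > tol_noslip:
            raise SolverError(
                f"no-slip residual {resid:.3e} exceeds tolerance {tol_noslip:.1e}"
            )
    return sol


@dataclass
class WallTractionField:
    """Sampled traction the fluid exerts on the top wall z = +W.

    ``traction`` rows are (t_x, t_y) in pN um^-2 at points (x, y);
    ``weights`` are quadrature areas in um^2 summing to the covered area.
    """

    x: np.ndarray
    y: np.ndarray
    traction: np.ndarray
    weights: np.ndarray
    window: tuple[float, float]
    method: str

    def total_force(self) -> np.ndarray:
        """Net in-plane force (F_x, F_y) on the covered window, pN."""
        return self.traction.T @ self.weights

    def edge_decay_ratio(self) -> float:
        """Max |t| on the outermost axial sample rows over the global max."""
        tmag = np.linalg.norm(self.traction, axis=1)
        if tmag.max() == 0.0:
            return 0.0
        lo, hi = self.window
        span = hi - lo
        edge = (self.x < lo + 0.05 * span) | (self.x > hi - 0.05 * span)
        if not edge.any():
            return 1.0
        return float(tmag[edge].max() / tmag.max())


def top_wall_traction(
    solution: ChannelFlowSolution,
    axial_window: tuple[float, float] | None = None,
    resolution: float | None = None,
    method: str = "panel",
) -> WallTractionField:
    """Traction carried to the puck through the top wall.

    ``method="panel"`` (default) reads the traction off the solved panel
    densities (traction on the puck = -density), which is exact for the
    discretized representation.  ``method="finite_difference"`` applies the
    defining relation t = -mu (dU_x/dz, dU_y/dz) at z = +W by one-sided
    differencing of the velocity evaluator with step h/4; because the probe
    then sits inside the regularization layer this variant systematically
    underestimates the traction and is provided as a diagnostic only.
    """
    geo = solution.geometry
    lo_t, hi_t = geo.axial_window
    if axial_window is None:
        axial_window = (lo_t, hi_t)
    lo, hi = axial_window
    if lo < lo_t - 1e-9 or hi > hi_t + 1e-9:
        raise GeometryError("axial window exceeds the truncation window")
    if method == "panel":
        top = solution.panel_wall_id == WALL_TOP
        sel = top & (solution.panel_centers[:, 0] >= lo) & (
            solution.panel_centers[:, 0] <= hi
        )
        pts = solution.panel_centers[sel]
        tr = -solution.densities[sel][:, :2]
        wts = solution.panel_areas[sel]
        x, y = pts[:, 0], pts[:, 1]
    elif method == "finite_difference":
        W = geo.half_width
        h = resolution if resolution is not None else geo.panel_size
        nx = max(int(round((hi - lo) / h)), 1)
        ny = max(int(round(2 * W / h)), 1)
        hx, hy = (hi - lo) / nx, 2 * W / ny
        xg = lo + hx * (np.arange(nx) + 0.5)
        yg = -W + hy * (np.arange(ny) + 0.5)
        X, Y = np.meshgrid(xg, yg, indexing="ij")
        x, y = X.ravel(), Y.ravel()
        delta = geo.panel_size / 4.0
        probe = np.stack([x, y, np.full_like(x, W - delta)], axis=1)
        u = solution.velocity(probe)
        # no-slip holds at the wall, so dU/dz ~ (0 - U(W - delta)) / delta and
        # the traction on the puck t = -mu dU/dz = -mu U(W - delta)/delta...
        # sign: t = -mu * (U(W) - U(W-d))/d = +mu U(W-d)/d
        tr = solution.geometry.viscosity * u[:, :2] / delta
        wts = np.full_like(x, hx * hy)
    else:
        raise ValueError(f"unknown traction method {method!r}")
    fieldv = WallTractionField(
        x=x, y=y, traction=tr, weights=wts, window=(lo, hi), method=method
    )
    return fieldv


def puck_torque_from_traction(
    traction: WallTractionField, puck_center: tuple[float, float] = (0.0, 0.0),
    decay_tol: float = 1e-2,
) -> float:
    """Vertical torque (pN um) on the puck about ``puck_center``.

    Integrates (r - r_C) x t over the sampled window.  If the traction has
    not decayed at the window edges (edge max above ``decay_tol`` of the
    global max) the support is truncated and a warning is emitted.
    """
    xc, yc = puck_center
    tau = np.sum(
        ((traction.x - xc) * traction.traction[:, 1]
         - (traction.y - yc) * traction.traction[:, 0]) * traction.weights
    )
    if traction.edge_decay_ratio() > decay_tol:
        warnings.warn(
            "traction not decayed at the integration-window edges; "
            "torque may be truncated",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(tau)


@dataclass(frozen=True)
class LambdaResult:
    """Richardson-extrapolated torque-transmission constant."""

    value: float
    uncertainty: float
    per_level: dict[float, float]

    def __post_init__(self):
        if not self.value > 0:
            raise SolverError("Lambda must be positive")


def _lambda_at_resolution(geometry: ChannelGeometry, h: float) -> float:
    geo = replace(geometry, panel_size=h)
    src = Rotlet(position=(0.0, 0.0, 0.0), torque=(1.0, 0.0, 0.0))
    sol = solve_channel_flow(geo, [src])
    # For a unit axial rotlet the net y-force on the puck acts at the rotlet's
    # axial station, so Lambda = -W * F_y(top wall) / Gamma_M.
    top = sol.panel_wall_id == WALL_TOP
    f_y = np.sum(-sol.densities[top, 1] * sol.panel_areas[top])
    return -geometry.half_width * f_y / 1.0


def compute_lambda(
    geometry: ChannelGeometry,
    refinement_levels: Sequence[float] | None = None,
) -> LambdaResult:
    """Torque-transmission constant by mesh refinement and extrapolation.

    A unit axial rotlet is placed on the duct centerline, the no-slip panel
    system is solved at each panel size in ``refinement_levels``, and the
    top-wall traction integral is extrapolated linearly in the panel size
    (the regularized single-layer converges at first order in h with the
    regularization tied to h).  At least two levels are required; a
    non-shrinking refinement sequence raises ``SolverError`` carrying the
    per-level values.
    """
    W = geometry.half_width
    if refinement_levels is None:
        refinement_levels = [W / 4.0, W / 5.0, W / 6.0]
    hs = sorted(float(h) for h in refinement_levels)[::-1]
    if len(hs) < 2:
        raise ValueError("at least two refinement levels are required")
    values = {}
    for h in hs:
        values[h] = _lambda_at_resolution(geometry, h)
        logger.info("Lambda at h=%.4g um: %.5f", h, values[h])
    lam = np.array([values[h] for h in hs])
    diffs = np.abs(np.diff(lam))
    if len(diffs) >= 2 and np.any(diffs[1:] > 1.25 * diffs[:-1]):
        raise SolverError(f"refinement sequence not converging: {values}")
    harr = np.array(hs)
    coeffs, res, *_ = np.polyfit(harr, lam, 1, full=True)
    extrap = float(coeffs[1])
    # uncertainty: extrapolation distance from the finest level, plus fit scatter
    fit_rms = float(np.sqrt(res[0] / len(hs))) if len(res) and len(hs) > 2 else 0.0
    unc = 0.5 * abs(lam[-1] - extrap) + fit_rms
    return LambdaResult(value=extrap, uncertainty=unc, per_level=values)


def mirror_rotlet(r: Rotlet, plane_x: float) -> Rotlet:
    """Image of a rotlet under reflection through the plane x = plane_x.

    The position is mirrored; the torque, a pseudovector, keeps its axial
    (x) component and flips the transverse ones.  For an axial torque dipole
    the image system cancels the normal velocity on the mirror plane, which
    models the closed end wall of a chamber.
    """
    px, py, pz = r.position
    tx, ty, tz = r.torque
    return Rotlet(position=(2.0 * plane_x - px, py, pz), torque=(tx, -ty, -tz))


def closed_chamber_solution(
    geometry: ChannelGeometry,
    sources: Sequence[Rotlet],
    tol_noslip: float = 1e-3,
    explicit_end_wall: bool = False,
) -> ChannelFlowSolution:
    """Duct flow with a dead-end wall at ``geometry.dead_end``.

    By default the no-flux condition at the dead end is imposed by
    augmenting each source with its mirror image through the end-wall plane
    (the combined flow is reflection-symmetric, so the normal velocity
    vanishes there); the duct-wall no-slip system is then solved for the
    four-rotlet forcing.  ``explicit_end_wall=True`` instead panels the end
    wall and enforces full no-slip on it, as an independent check.
    """
    if geometry.dead_end is None:
        raise GeometryError("closed_chamber_solution requires geometry.dead_end")
    xw = geometry.dead_end
    for r in sources:
        if r.position[0] >= xw:
            raise GeometryError("sources must lie on the open side of the dead end")
        if not geometry.contains(r.position):
            raise GeometryError("source outside the duct")
    if explicit_end_wall:
        return solve_channel_flow(
            geometry, sources, tol_noslip=tol_noslip, _end_wall=True
        )
    images = tuple(mirror_rotlet(r, xw) for r in sources)
    return solve_channel_flow(
        geometry, sources, tol_noslip=tol_noslip, _extra_sources=images
    )


def dead_end_normal_velocity(solution: ChannelFlowSolution, n: int = 9) -> float:
    """Max |u_x| on the dead-end plane, normalized by the rotlet scale."""
    geo = solution.geometry
    if geo.dead_end is None:
        raise GeometryError("solution has no dead end")
    W = geo.half_width
    s = np.linspace(-0.8 * W, 0.8 * W, n)
    Y, Z = np.meshgrid(s, s, indexing="ij")
    pts = np.stack([np.full(Y.size, geo.dead_end), Y.ravel(), Z.ravel()], axis=1)
    u = solution.velocity(pts)
    return float(np.abs(u[:, 0]).max() / solution.velocity_scale())


def closed_chamber_correction(
    geometry: ChannelGeometry,
    dipole_length: float,
    body_length: float,
    lam: float,
    motor_torque: float = 1.0,
    gap: float | None = None,
    puck_center_offset: float = 0.5,
) -> float:
    """Dimensionless closed-chamber multiplier on the open-channel torque.

    Places the torque dipole with its leading rotlet a distance ``gap``
    (default: half the body length) short of the dead end, solves the
    image-augmented system, integrates the top-wall traction over the
    physical side of the chamber only, and divides by the open-channel
    dipole torque -Lambda * l_D / W * Gamma_M.  The puck centre is taken
    ``puck_center_offset`` um beyond the dead end (the chamber terminates
    near the centre of the disc).
    """
    if geometry.dead_end is None:
        raise GeometryError("closed_chamber_correction requires geometry.dead_end")
    xw = geometry.dead_end
    if gap is None:
        gap = body_length / 2.0
    x1 = xw - gap
    x2 = x1 - dipole_length
    sources = [
        Rotlet(position=(x1, 0.0, 0.0), torque=(motor_torque, 0.0, 0.0)),
        Rotlet(position=(x2, 0.0, 0.0), torque=(-motor_torque, 0.0, 0.0)),
    ]
    sol = closed_chamber_solution(geometry, sources)
    lo, _ = geometry.axial_window
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        tr = top_wall_traction(sol, axial_window=(lo, xw))
        tau = puck_torque_from_traction(tr, puck_center=(xw + puck_center_offset, 0.0))
    open_torque = -lam * dipole_length / geometry.half_width * motor_torque
    return float(tau / open_torque)
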