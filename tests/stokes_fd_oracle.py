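"""Independent coarse finite-difference Stokes oracle for the BEM tests.

A staggered-grid (MAC) discretization of the Stokes equations in a no-slip
box [-Lx/2, Lx/2] x [-W, W] x [-W, W], forced by a regularized point torque
f = (Gamma/2) curl(phi_eps x_hat) with a Gaussian blob phi_eps (which carries
total torque Gamma exactly, independent of the blob width).  The saddle
system is assembled sparse and solved directly.  This shares no code or
discretization with the boundary-element solver it cross-checks.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla


class FdDuctSolution:
    """Staggered velocity fields plus sampling helpers."""

    def __init__(self, u, v, w, xf, xc, yf, yc, zf, zc, h, hx, mu, gamma):
        self.u, self.v, self.w = u, v, w
        self.xf, self.xc = xf, xc
        self.yf, self.yc = yf, yc
        self.zf, self.zc = zf, zc
        self.h, self.hx, self.mu, self.gamma = h, hx, mu, gamma

    def v_node(self, i, j, k):
        """u_y value and location at a y-face node."""
        return self.v[i, j, k], np.array([self.xc[i], self.yf[j], self.zc[k]])

    def top_wall_force_y(self):
        """Integral of mu * dU_y/dz over the top wall, one-sided quadratic."""
        n = len(self.yc)
        a1 = self.v[:, :, n - 1]  # z = W - h/2
        a2 = self.v[:, :, n - 2]  # z = W - 3h/2
        dvdz = -3.0 * a1 / self.h + a2 / (3.0 * self.h)
        wts = np.full(self.v.shape[1], self.h)
        wts[0] = wts[-1] = self.h / 2.0
        return self.mu * np.sum(dvdz * wts[None, :] * self.hx)

    def lambda_estimate(self, W=1.0):
        """Transmission constant Lambda = W * integral(mu dU_y/dz) / Gamma."""
        return W * self.top_wall_force_y() / self.gamma


def solve_duct_fd(nx=48, n=12, Lx=8.0, src=(0.0, 0.0, 0.0), mu=1.0,
                  gamma=1.0, eps_fac=1.5, W=1.0):
    """Solve the regularized-rotlet duct problem on an nx * n * n MAC grid."""
    hx = Lx / nx
    h = 2.0 * W / n
    nu = (nx + 1) * n * n
    nv = nx * (n + 1) * n
    nw = nx * n * (n + 1)

    def iu(i, j, k):
        return (i * n + j) * n + k

    def iv(i, j, k):
        return nu + (i * (n + 1) + j) * n + k

    def iw(i, j, k):
        return nu + nv + (i * n + j) * (n + 1) + k

    def ip(i, j, k):
        return nu + nv + nw + (i * n + j) * n + k

    N = nu + nv + nw + nx * n * n
    rows, cols, vals = [], [], []
    b = np.zeros(N)

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    eps = eps_fac * max(h, hx)
    sx, sy, sz = src

    def dblob(x, y, z, comp):
        r2 = (x - sx) ** 2 + (y - sy) ** 2 + (z - sz) ** 2
        phi = np.exp(-r2 / (2 * eps**2)) / ((2 * np.pi) ** 1.5 * eps**3)
        d = {0: x - sx, 1: y - sy, 2: z - sz}[comp]
        return -d / eps**2 * phi

    xf = -Lx / 2 + hx * np.arange(nx + 1)
    xc = xf[:-1] + hx / 2
    yf = -W + h * np.arange(n + 1)
    yc = yf[:-1] + h / 2
    zf = yf.copy()
    zc = yc.copy()

    # u-momentum (f_x = 0)
    for i in range(nx + 1):
        for j in range(n):
            for k in range(n):
                r = iu(i, j, k)
                if i == 0 or i == nx:
                    add(r, r, 1.0)
                    continue
                add(r, r, -2 * mu / hx**2)
                add(r, iu(i - 1, j, k), mu / hx**2)
                add(r, iu(i + 1, j, k), mu / hx**2)
                for dj in (-1, 1):
                    jj = j + dj
                    if 0 <= jj < n:
                        add(r, iu(i, jj, k), mu / h**2)
                        add(r, r, -mu / h**2)
                    else:
                        add(r, r, -2 * mu / h**2)  # ghost = -u (no-slip wall)
                for dk in (-1, 1):
                    kk = k + dk
                    if 0 <= kk < n:
                        add(r, iu(i, j, kk), mu / h**2)
                        add(r, r, -mu / h**2)
                    else:
                        add(r, r, -2 * mu / h**2)
                add(r, ip(i, j, k), -1.0 / hx)
                add(r, ip(i - 1, j, k), 1.0 / hx)
    # v-momentum: f_y = (gamma/2) d(phi)/dz
    for i in range(nx):
        for j in range(n + 1):
            for k in range(n):
                r = iv(i, j, k)
                if j == 0 or j == n:
                    add(r, r, 1.0)
                    continue
                add(r, r, -2 * mu / h**2)
                add(r, iv(i, j - 1, k), mu / h**2)
                add(r, iv(i, j + 1, k), mu / h**2)
                for di in (-1, 1):
                    ii = i + di
                    if 0 <= ii < nx:
                        add(r, iv(ii, j, k), mu / hx**2)
                        add(r, r, -mu / hx**2)
                    else:
                        add(r, r, -2 * mu / hx**2)
                for dk in (-1, 1):
                    kk = k + dk
                    if 0 <= kk < n:
                        add(r, iv(i, j, kk), mu / h**2)
                        add(r, r, -mu / h**2)
                    else:
                        add(r, r, -2 * mu / h**2)
                add(r, ip(i, j, k), -1.0 / h)
                add(r, ip(i, j - 1, k), 1.0 / h)
                b[r] = -(gamma / 2.0) * dblob(xc[i], yf[j], zc[k], 2)
    # w-momentum: f_z = -(gamma/2) d(phi)/dy
    for i in range(nx):
        for j in range(n):
            for k in range(n + 1):
                r = iw(i, j, k)
                if k == 0 or k == n:
                    add(r, r, 1.0)
                    continue
                add(r, r, -2 * mu / h**2)
                add(r, iw(i, j, k - 1), mu / h**2)
                add(r, iw(i, j, k + 1), mu / h**2)
                for di in (-1, 1):
                    ii = i + di
                    if 0 <= ii < nx:
                        add(r, iw(ii, j, k), mu / hx**2)
                        add(r, r, -mu / hx**2)
                    else:
                        add(r, r, -2 * mu / hx**2)
                for dj in (-1, 1):
                    jj = j + dj
                    if 0 <= jj < n:
                        add(r, iw(i, jj, k), mu / h**2)
                        add(r, r, -mu / h**2)
                    else:
                        add(r, r, -2 * mu / h**2)
                add(r, ip(i, j, k), -1.0 / h)
                add(r, ip(i, j, k - 1), 1.0 / h)
                b[r] = +(gamma / 2.0) * dblob(xc[i], yc[j], zf[k], 1)
    # continuity
    for i in range(nx):
        for j in range(n):
            for k in range(n):
                r = ip(i, j, k)
                add(r, iu(i + 1, j, k), 1.0 / hx)
                add(r, iu(i, j, k), -1.0 / hx)
                add(r, iv(i, j + 1, k), 1.0 / h)
                add(r, iv(i, j, k), -1.0 / h)
                add(r, iw(i, j, k + 1), 1.0 / h)
                add(r, iw(i, j, k), -1.0 / h)
    # pin one pressure value
    r0 = ip(0, 0, 0)
    keep = [(r, c, v) for r, c, v in zip(rows, cols, vals) if r != r0]
    keep.append((r0, r0, 1.0))
    b[r0] = 0.0
    rows, cols, vals = zip(*keep)
    A = sp.csr_matrix((vals, (rows, cols)), shape=(N, N))
    sol = spla.spsolve(A, b)
    u = sol[:nu].reshape(nx + 1, n, n)
    v = sol[nu:nu + nv].reshape(nx, n + 1, n)
    w = sol[nu + nv:nu + nv + nw].reshape(nx, n, n + 1)
    return FdDuctSolution(u, v, w, xf, xc, yf, yc, zf, zc, h, hx, mu, gamma)
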