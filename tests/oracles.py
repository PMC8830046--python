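"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the committor
oracle solves the phase-space backward Kolmogorov equation by sparse
finite differences, and the Steinhardt oracle uses the Legendre
addition theorem instead of explicit spherical harmonics.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve
from scipy.special import eval_legendre
from scipy.stats import norm


def committor_pde_1d(
    barrier_height: float,
    friction: float,
    temperature: float,
    mass: float,
    x_absorb: float,
    nx: int = 241,
    nv: int = 121,
    v_max: float = 4.5,
):
    """Committor of the underdamped double well from the backward
    Kolmogorov equation on the (x, v) phase plane.

    Dynamics: dx = v dt, dv = (F(x)/m - gamma v) dt + sqrt(2 gamma T/m) dW
    with F = -dV/dx, V = h (x^2-1)^2.  q solves

        v q_x + (F/m - gamma v) q_v + (gamma T / m) q_vv = 0

    with q = 1 absorbed at x >= +x_absorb and q = 0 at x <= -x_absorb,
    zero-derivative closure at |v| = v_max.  Returns a function
    p(x0): the Maxwell-Boltzmann average of q(x0, v) over v, i.e. the
    committor of a configuration with randomized velocities.
    """
    xs = np.linspace(-x_absorb, x_absorb, nx)
    vs = np.linspace(-v_max, v_max, nv)
    dx = xs[1] - xs[0]
    dv = vs[1] - vs[0]
    h = barrier_height
    force = lambda x: -4.0 * h * (x**2 - 1.0) * x  # noqa: E731
    D = friction * temperature / mass

    def idx(i, j):
        return i * nv + j

    rows, cols, vals = [], [], []
    rhs = np.zeros(nx * nv)

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i, x in enumerate(xs):
        for j, v in enumerate(vs):
            r = idx(i, j)
            if i == 0:
                add(r, r, 1.0)      # q = 0 at the B boundary
                continue
            if i == nx - 1:
                add(r, r, 1.0)
                rhs[r] = 1.0        # q = 1 at the A boundary
                continue
            # advection in x: one-sided difference along the drift
            # direction (the backward operator looks forward in time)
            if v >= 0:
                add(r, idx(i + 1, j), v / dx)
                add(r, r, -v / dx)
            else:
                add(r, r, v / dx)
                add(r, idx(i - 1, j), -v / dx)
            drift = force(x) / mass - friction * v
            # advection in v, same upwinding rule
            if drift >= 0:
                jn = min(j + 1, nv - 1)
                add(r, idx(i, jn), drift / dv)
                add(r, r, -drift / dv)
            else:
                jn = max(j - 1, 0)
                add(r, r, drift / dv)
                add(r, idx(i, jn), -drift / dv)
            # diffusion in v (central; one-sided drop at the v edges)
            if 0 < j < nv - 1:
                add(r, idx(i, j - 1), D / dv**2)
                add(r, idx(i, j + 1), D / dv**2)
                add(r, r, -2.0 * D / dv**2)
    A = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(nx * nv, nx * nv)
    )
    q = spsolve(A, rhs).reshape(nx, nv)
    mb = norm.pdf(vs, scale=np.sqrt(temperature / mass))
    mb = mb / mb.sum()

    def p_of_x(x0: float) -> float:
        qx = np.array([np.interp(x0, xs, q[:, j]) for j in range(nv)])
        return float(qx @ mb)

    return p_of_x


def steinhardt_legendre(vectors: np.ndarray, l: int) -> float:
    """Steinhardt q_l via the addition theorem:

        q_l^2 = (1/N^2) sum_{i,j} P_l(u_i . u_j)

    which avoids spherical harmonics entirely.
    """
    u = np.asarray(vectors, dtype=float)
    u = u / np.linalg.norm(u, axis=1)[:, None]
    dots = np.clip(u @ u.T, -1.0, 1.0)
    return float(np.sqrt(np.maximum(eval_legendre(l, dots).mean(), 0.0)))
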