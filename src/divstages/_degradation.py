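"""Fast fixed-grid integrator for the degradation-variant master equation.

The degradation model is the one variant whose master equation has no closed
Poisson-counting solution (stage loss makes the process state-dependent), so
fitting it requires thousands of small linear ODE solves.  This module holds a
classical RK4 integrator with adaptive substepping (substep bounded by
``stability / max total rate``), jitted with numba when available.  The scipy
LSODA path in :mod:`divstages.master_equation` is the reference it is tested
against, and the fallback when numba is not installed.
"""
from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    njit = None
    HAVE_NUMBA = False

#: substep control: RK4 substep length <= STABILITY / (max total transition rate)
STABILITY = 0.05
#: once P_M exceeds this, the solution is frozen (absorption is complete and
#: k_+ keeps growing exponentially, so further substepping is pure waste)
ABSORBED = 1.0 - 1e-12


def _propagate_py(k, gamma, M, mu, s_b, t_grid):
    """Pure-numpy twin of the jitted kernel (used when numba is unavailable)."""
    n = t_grid.size
    P = np.zeros((n, M + 1))
    P[0, 0] = 1.0
    cur = P[0].copy()
    mdown = np.arange(1, M)  # states that can lose a stage (M is absorbing)

    def rhs(t, p):
        kp = k * s_b * np.exp(mu * t)
        out = np.zeros(M + 1)
        fu = kp * p[:M]
        out[1:] += fu
        out[:M] -= fu
        if gamma > 0.0 and M >= 2:
            fd = gamma * mdown * p[1:M]
            out[0 : M - 1] += fd
            out[1:M] -= fd
        return out

    for i in range(1, n):
        if cur[M] >= ABSORBED:
            P[i:] = cur
            break
        t0 = t_grid[i - 1]
        h = t_grid[i] - t0
        rmax = k * s_b * np.exp(mu * t_grid[i]) + gamma * M
        nsub = int(h * rmax / STABILITY) + 1
        dt = h / nsub
        for j in range(nsub):
            ta = t0 + j * dt
            k1 = rhs(ta, cur)
            k2 = rhs(ta + 0.5 * dt, cur + 0.5 * dt * k1)
            k3 = rhs(ta + 0.5 * dt, cur + 0.5 * dt * k2)
            k4 = rhs(ta + dt, cur + dt * k3)
            cur = cur + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        P[i] = cur
    return P


if HAVE_NUMBA:

    @njit(cache=True)
    def _rhs_nb(t, p, out, k, gamma, M, mu, s_b):  # pragma: no cover - jitted
        kp = k * s_b * np.exp(mu * t)
        for m in range(M + 1):
            out[m] = 0.0
        for m in range(M):
            f = kp * p[m]
            out[m] -= f
            out[m + 1] += f
        for m in range(1, M):
            f = gamma * m * p[m]
            out[m] -= f
            out[m - 1] += f

    @njit(cache=True)
    def _propagate_nb(k, gamma, M, mu, s_b, t_grid, stability):  # pragma: no cover
        n = t_grid.size
        P = np.zeros((n, M + 1))
        P[0, 0] = 1.0
        cur = np.zeros(M + 1)
        cur[0] = 1.0
        k1 = np.empty(M + 1)
        k2 = np.empty(M + 1)
        k3 = np.empty(M + 1)
        k4 = np.empty(M + 1)
        tmp = np.empty(M + 1)
        for i in range(1, n):
            if cur[M] >= ABSORBED:
                for ii in range(i, n):
                    for m in range(M + 1):
                        P[ii, m] = cur[m]
                break
            t0 = t_grid[i - 1]
            h = t_grid[i] - t0
            rmax = k * s_b * np.exp(mu * t_grid[i]) + gamma * M
            nsub = int(h * rmax / stability) + 1
            dt = h / nsub
            for j in range(nsub):
                ta = t0 + j * dt
                _rhs_nb(ta, cur, k1, k, gamma, M, mu, s_b)
                for m in range(M + 1):
                    tmp[m] = cur[m] + 0.5 * dt * k1[m]
                _rhs_nb(ta + 0.5 * dt, tmp, k2, k, gamma, M, mu, s_b)
                for m in range(M + 1):
                    tmp[m] = cur[m] + 0.5 * dt * k2[m]
                _rhs_nb(ta + 0.5 * dt, tmp, k3, k, gamma, M, mu, s_b)
                for m in range(M + 1):
                    tmp[m] = cur[m] + dt * k3[m]
                _rhs_nb(ta + dt, tmp, k4, k, gamma, M, mu, s_b)
                for m in range(M + 1):
                    cur[m] += (dt / 6.0) * (k1[m] + 2.0 * k2[m] + 2.0 * k3[m] + k4[m])
            for m in range(M + 1):
                P[i, m] = cur[m]
        return P


def propagate(k: float, gamma: float, M: int, mu: float, s_b: float, t_grid: np.ndarray) -> np.ndarray:
    """Integrate the degradation master equation on ``t_grid``.

    Returns the ``(len(t_grid), M + 1)`` matrix of stage probabilities starting
    from ``P_m(0) = delta_{m,0}``.
    """
    t_grid = np.ascontiguousarray(t_grid, dtype=float)
    if HAVE_NUMBA:
        return _propagate_nb(float(k), float(gamma), int(M), float(mu), float(s_b), t_grid, STABILITY)
    return _propagate_py(float(k), float(gamma), int(M), float(mu), float(s_b), t_grid)
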