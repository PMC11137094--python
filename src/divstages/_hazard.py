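"""Cumulative per-size stage hazard for the commitment-size rate law.

In the size coordinate the pure-birth stage process has per-unit-size hazard
``h(s) = k_+(s) / (mu s)``.  For the commitment variant the cumulative hazard
has no closed form, so we tabulate ``G(s) = int_{s_lo}^{s} du / (1 + (s0/u)^beta)``
once per (s0, beta) on a dense log grid; then
``Lambda(s_b -> s_d) = (k/mu) * (G(s_d) - G(s_b))``.  The table serves both the
simulator (hazard inversion) and the pointwise likelihood.
"""
from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.integrate import cumulative_trapezoid

#: table span in normalized size units; mother-machine data live in ~[0.3, 5]
S_LO = 1e-3
S_HI = 1e4
N_TABLE = 20000


@lru_cache(maxsize=128)
def commitment_hazard_table(s0: float, beta: float) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(u_grid, G)`` with G non-decreasing on a dense log-spaced grid."""
    u = np.geomspace(S_LO, S_HI, N_TABLE)
    with np.errstate(over="ignore", under="ignore"):
        gate = 1.0 / (1.0 + (s0 / u) ** beta)
    G = cumulative_trapezoid(gate, u, initial=0.0)
    return u, np.maximum.accumulate(G)


def commitment_G(s, s0: float, beta: float):
    """Interpolated ``G(s)`` (vectorized); sizes below the table floor map to 0."""
    u, G = commitment_hazard_table(float(s0), float(beta))
    return np.interp(np.asarray(s, dtype=float), u, G, left=0.0)


def invert_commitment_G(G_target, s0: float, beta: float):
    """Size at which the tabulated cumulative hazard reaches ``G_target``."""
    u, G = commitment_hazard_table(float(s0), float(beta))
    G_target = np.asarray(G_target, dtype=float)
    if np.any(G_target > G[-1]):
        raise ArithmeticError(
            f"hazard inversion left the tabulated size range (target {G_target.max():.4g} "
            f"> G({S_HI:g}) = {G[-1]:.4g}); size at division would exceed {S_HI:g}"
        )
    return np.interp(G_target, G, u)
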