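"""Master-equation solver and the densities derived from it.

Given a birth size ``s_b``, the stage-count probabilities ``P_m(t)`` obey the
(M+1)-state forward Kolmogorov (master) equation

    dP_0/dt = -k_+ P_0 + k_-(1) P_1
    dP_m/dt =  k_+ P_{m-1} - k_+ P_m - k_-(m) P_m + k_-(m+1) P_{m+1}
    dP_M/dt =  k_+ P_{M-1}                 (M is absorbing: division fired)

with ``k_+ = k_+(s_b e^{mu t})`` time-varying through growth and the initial
condition ``P_m(0) = delta_{m,0}``.  ``P_M(t)`` is the CDF of the division time
``tau``; its density is ``rho_tau(t) = k_+ P_{M-1}`` (never a numerical
derivative).  The change of variables ``s = s_b e^{mu t}`` turns ``rho_tau``
into the size-at-division density ``rho_sd(s | s_b) = rho_tau(t(s)) / (mu s)``,
from which moments, the mean added size ``<Delta> = <s_d> - s_b`` and the noise
``CV2_Delta = var(Delta) / <Delta>^2`` follow by quadrature.

Solver strategies
-----------------
For pure-birth variants (``k_- = 0``: adder, power_law, commitment) the stage
count is an inhomogeneous Poisson counting process, so the master equation has
the exact solution ``P_m(t) = Pois(m; Lambda(t))`` for ``m < M`` with
``Lambda(t) = int_0^t k_+(s_b e^{mu u}) du``; we evaluate it by cumulative
quadrature ("analytic" method, the default).  The degradation variant is
integrated numerically (numba RK4 kernel, scipy LSODA fallback/reference).
Both numerical paths use a two-pass horizon search: double the horizon until
``P_M`` reaches the completion threshold, then re-solve on a grid trimmed to
the absorption time so the division window is well resolved.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid, solve_ivp, trapezoid
from scipy.interpolate import PchipInterpolator
from scipy.special import gammaln

from . import _degradation
from .models import DivisionModel, GrowthLaw

__all__ = [
    "StageDistribution",
    "DivisionTimeDensity",
    "SizeAtDivisionDensity",
    "NoiseSummary",
    "IncompleteAbsorptionError",
    "ExtrapolationError",
    "ConsistencyError",
    "DegenerateDensityError",
    "solve_stages",
    "division_time_density",
    "size_at_division_density",
    "moments",
    "noise_summary",
    "strategy_curves",
    "division_size_density",
    "mean_division_size",
]

DEFAULT_COMPLETION = 1.0 - 1e-6
#: log-density floor keeping log-likelihoods finite
LOG_FLOOR = math.log(1e-300)


class IncompleteAbsorptionError(RuntimeError):
    """P_M failed to reach the completion threshold within the horizon cap."""

    def __init__(self, mass: float, horizon: float):
        self.mass = mass
        self.horizon = horizon
        super().__init__(
            f"division probability reached only {mass:.8f} at horizon t={horizon:.3g}"
        )


class ExtrapolationError(ValueError):
    """Requested size maps to a time beyond the solved horizon."""


class ConsistencyError(ValueError):
    """Solution and model/growth objects do not belong together."""


class DegenerateDensityError(ValueError):
    """Density has non-positive mean added size."""


# --------------------------------------------------------------------------- types
@dataclass
class StageDistribution:
    """Solved ``P_m(t)`` trajectory for one birth size."""

    s_b: float
    t_grid: np.ndarray  # strictly increasing, starts at 0
    P: np.ndarray       # shape (len(t_grid), M + 1)
    model: DivisionModel
    growth: GrowthLaw
    method: str = "analytic"

    @property
    def M(self) -> int:
        return self.P.shape[1] - 1

    @property
    def completion(self) -> float:
        """Final value of the division-time CDF ``P_M``."""
        return float(self.P[-1, -1])

    def p_m(self, m: int) -> np.ndarray:
        return self.P[:, m]


@dataclass
class DivisionTimeDensity:
    """Division-time density ``rho_tau(t) = k_+ P_{M-1}`` on the solved grid."""

    s_b: float
    t_grid: np.ndarray
    rho_tau: np.ndarray
    completion: float
    model: DivisionModel
    growth: GrowthLaw

    def cdf(self) -> np.ndarray:
        """Cumulative trapezoid of ``rho_tau`` (should reproduce ``P_M``)."""
        return cumulative_trapezoid(self.rho_tau, self.t_grid, initial=0.0)

    def to_frame(self) -> pd.DataFrame:
        """Two-column table (time, density) for plotting/export."""
        return pd.DataFrame({"t": self.t_grid, "rho_tau": self.rho_tau})


@dataclass
class SizeAtDivisionDensity:
    """Conditional size-at-division density ``rho_sd(s | s_b)`` on a size grid."""

    s_b: float
    s_grid: np.ndarray
    rho_sd: np.ndarray
    completion: float
    renormalized: bool = field(default=False)

    def moment(self, alpha: float, renormalize: bool = True) -> float:
        """alpha-th moment ``<s_d^alpha>`` by trapezoidal quadrature.

        Residual probability mass beyond the solver horizon (at most
        ``1 - completion``) is folded in by renormalizing, keeping the density
        proper; a warning flags completions that are materially short.
        """
        mass = trapezoid(self.rho_sd, self.s_grid)
        if mass <= 0:
            raise DegenerateDensityError("density integrates to zero")
        if self.completion < 0.999:
            warnings.warn(
                f"size-at-division density completion is only {self.completion:.4f}; "
                "moments are renormalized over the resolved mass",
                RuntimeWarning,
                stacklevel=2,
            )
        raw = trapezoid(self.s_grid**alpha * self.rho_sd, self.s_grid)
        return float(raw / mass) if renormalize else float(raw)

    def mean_added(self) -> float:
        return self.moment(1.0) - self.s_b

    def to_frame(self) -> pd.DataFrame:
        """Two-column table (size, density) for plotting/export."""
        return pd.DataFrame({"s": self.s_grid, "rho_sd": self.rho_sd})


@dataclass(frozen=True)
class NoiseSummary:
    """Added-size summary: ``<Delta>``, ``var(Delta)``, ``CV2 = var/<Delta>^2``."""

    mean_added: float
    var_added: float
    cv2: float


# --------------------------------------------------------------------------- solver
def _poisson_matrix(Lam: np.ndarray, M: int) -> np.ndarray:
    """Stage probabilities of the pure-birth process from the cumulative hazard."""
    m = np.arange(M)
    with np.errstate(divide="ignore", invalid="ignore"):
        logLam = np.log(Lam)
        logP = m[None, :] * logLam[:, None] - Lam[:, None] - gammaln(m + 1)[None, :]
    P = np.exp(logP)
    zero = Lam == 0.0
    if np.any(zero):
        P[zero, :] = 0.0
        P[zero, 0] = 1.0
    PM = np.clip(1.0 - P.sum(axis=1), 0.0, 1.0)
    return np.column_stack([P, PM])


def _two_pass_solve(
    propagate: Callable[[np.ndarray], np.ndarray],
    T0: float,
    T_cap: float,
    completion: float,
    n_coarse: int,
    n_fine: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Horizon search (doubling) + grid trimmed to the absorption time."""
    T = min(T0, T_cap)
    last_mass = 0.0
    while True:
        t = np.linspace(0.0, T, n_coarse)
        P = propagate(t)
        PM = P[:, -1]
        last_mass = float(PM[-1])
        if last_mass >= completion:
            idx = int(np.searchsorted(PM, completion))
            idx = min(idx, len(t) - 1)
            T_trim = min(t[idx] * 1.05, T) if t[idx] > 0 else T
            tf = np.linspace(0.0, T_trim, n_fine)
            Pf = propagate(tf)
            if Pf[-1, -1] >= completion:
                return tf, Pf
            tf = np.linspace(0.0, T, n_fine)
            Pf = propagate(tf)
            if Pf[-1, -1] >= completion:
                return tf, Pf
            last_mass = float(Pf[-1, -1])
        if T >= T_cap:
            raise IncompleteAbsorptionError(last_mass, T)
        T = min(2.0 * T, T_cap)


def _propagate_pure_birth(model: DivisionModel, growth: GrowthLaw, s_b: float):
    def propagate(t: np.ndarray) -> np.ndarray:
        kp = model.rate_up(growth.size_at(s_b, t))
        Lam = cumulative_trapezoid(kp, t, initial=0.0)
        return _poisson_matrix(Lam, model.M)

    return propagate


def _propagate_ode(model: DivisionModel, growth: GrowthLaw, s_b: float):
    M = model.M
    gam = float(model.gamma) if model.variant == "degradation" else 0.0
    mdown = np.arange(1, M)
    mu = growth.mu
    k = model.k

    def kp_of(t: float) -> float:
        return model.rate_up(s_b * math.exp(mu * t))

    def rhs(t, p):
        kp = kp_of(t)
        out = np.zeros(M + 1)
        fu = kp * p[:M]
        out[1:] += fu
        out[:M] -= fu
        if gam > 0.0 and M >= 2:
            fd = gam * mdown * p[1:M]
            out[0 : M - 1] += fd
            out[1:M] -= fd
        return out

    def jac(t, p):
        kp = kp_of(t)
        J = np.zeros((M + 1, M + 1))
        idx = np.arange(M)
        J[idx, idx] -= kp
        J[idx + 1, idx] += kp
        if gam > 0.0 and M >= 2:
            J[mdown, mdown] -= gam * mdown
            J[mdown - 1, mdown] += gam * mdown
        return J

    p0 = np.zeros(M + 1)
    p0[0] = 1.0

    def propagate(t: np.ndarray) -> np.ndarray:
        sol = solve_ivp(
            rhs,
            (t[0], t[-1]),
            p0,
            method="LSODA",
            t_eval=t,
            jac=jac,
            rtol=1e-8,
            atol=1e-12,
        )
        if not sol.success:  # pragma: no cover - defensive
            raise RuntimeError(f"master-equation integration failed: {sol.message}")
        return np.clip(sol.y.T, 0.0, 1.0)

    return propagate


def _propagate_degradation_fast(model: DivisionModel, growth: GrowthLaw, s_b: float):
    def propagate(t: np.ndarray) -> np.ndarray:
        P = _degradation.propagate(model.k, model.gamma, model.M, growth.mu, s_b, t)
        return np.clip(P, 0.0, 1.0)

    return propagate


def solve_stages(
    model: DivisionModel,
    growth: GrowthLaw,
    s_b: float,
    *,
    horizon: float | None = None,
    n_points: int | None = None,
    completion: float = DEFAULT_COMPLETION,
    max_doublings: float = 80.0,
    method: str = "auto",
) -> StageDistribution:
    """Solve the master equation for ``P_m(t)`` at birth size ``s_b``.

    Parameters
    ----------
    horizon : float, optional
        Initial integration horizon (default 10 mean doubling times).  Doubled
        until ``P_M(horizon) >= completion`` up to ``max_doublings`` doubling
        times, after which :class:`IncompleteAbsorptionError` is raised.
    n_points : int, optional
        Output grid size (default 4000 for the analytic path, 2000 otherwise).
    method : {"auto", "analytic", "ode", "fast"}
        "analytic" is the exact Poisson-counting solution (pure-birth variants
        only); "ode" is scipy LSODA; "fast" is the jitted RK4 degradation
        kernel.  "auto" picks analytic for pure-birth models and the fast
        kernel (scipy fallback) for degradation.
    """
    if s_b <= 0:
        raise ValueError("birth size must be positive")
    if method == "auto":
        method = "analytic" if model.is_pure_birth else "fast"
    if method == "analytic":
        if not model.is_pure_birth:
            raise ValueError("analytic solution requires a pure-birth model (k_- = 0)")
        propagate = _propagate_pure_birth(model, growth, s_b)
        n_fine = n_points or 4000
    elif method == "ode":
        propagate = _propagate_ode(model, growth, s_b)
        n_fine = n_points or 2000
    elif method == "fast":
        if model.variant != "degradation" or not _degradation.HAVE_NUMBA:
            # analytic beats RK4 whenever it applies; scipy when numba is absent
            return solve_stages(
                model, growth, s_b,
                horizon=horizon, n_points=n_points, completion=completion,
                max_doublings=max_doublings,
                method="analytic" if model.is_pure_birth else "ode",
            )
        propagate = _propagate_degradation_fast(model, growth, s_b)
        n_fine = n_points or 2000
    else:
        raise ValueError(f"unknown method {method!r}")

    T0 = horizon if horizon is not None else 10.0 * growth.doubling_time
    T_cap = max_doublings * growth.doubling_time
    t_grid, P = _two_pass_solve(propagate, T0, T_cap, completion, n_coarse=400, n_fine=n_fine)
    return StageDistribution(s_b=float(s_b), t_grid=t_grid, P=P, model=model, growth=growth, method=method)


# --------------------------------------------------------------------------- densities
def division_time_density(
    stages: StageDistribution,
    model: DivisionModel | None = None,
    growth: GrowthLaw | None = None,
) -> DivisionTimeDensity:
    """``rho_tau(t) = k_+(s_b e^{mu t}) P_{M-1}(t)`` on the solved grid."""
    model = stages.model if model is None else model
    growth = stages.growth if growth is None else growth
    if model != stages.model or growth != stages.growth:
        raise ConsistencyError("stage distribution was solved for a different model/growth")
    kp = model.rate_up(growth.size_at(stages.s_b, stages.t_grid))
    rho = kp * stages.P[:, model.M - 1]
    return DivisionTimeDensity(
        s_b=stages.s_b,
        t_grid=stages.t_grid,
        rho_tau=rho,
        completion=stages.completion,
        model=model,
        growth=growth,
    )


def _interp_log_density(t_grid: np.ndarray, rho: np.ndarray, t_new: np.ndarray) -> np.ndarray:
    """Interpolate a density that spans orders of magnitude.

    Monotone (PCHIP) interpolation of log-density over the strictly positive
    region; values outside it fall back to linear interpolation of the density
    itself, so zeros near the support edges stay zero instead of leaking.
    """
    out = np.interp(t_new, t_grid, rho)
    pos = rho > 0.0
    if pos.sum() >= 2:
        i0, i1 = np.argmax(pos), len(rho) - np.argmax(pos[::-1]) - 1
        if np.all(pos[i0 : i1 + 1]):
            interp = PchipInterpolator(t_grid[i0 : i1 + 1], np.log(rho[i0 : i1 + 1]), extrapolate=False)
            inside = (t_new >= t_grid[i0]) & (t_new <= t_grid[i1])
            vals = interp(t_new[inside])
            out[inside] = np.exp(vals)
    return out


def size_at_division_density(
    dtd: DivisionTimeDensity,
    growth: GrowthLaw | None = None,
    s_b: float | None = None,
    s_grid: np.ndarray | None = None,
) -> SizeAtDivisionDensity:
    """Transform ``rho_tau`` into ``rho_sd(s | s_b) = rho_tau(t(s)) / (mu s)``.

    With ``s_grid=None`` the grid is the exact image ``s_b e^{mu t_grid}`` of
    the time grid, so no interpolation is involved.  A custom grid may not
    extend past the solved horizon (:class:`ExtrapolationError`); sizes below
    ``s_b`` get density zero.
    """
    growth = dtd.growth if growth is None else growth
    s_b = dtd.s_b if s_b is None else float(s_b)
    if growth != dtd.growth or not math.isclose(s_b, dtd.s_b, rel_tol=1e-12):
        raise ConsistencyError("division-time density belongs to a different growth law / birth size")
    mu = growth.mu
    if s_grid is None:
        s_grid = s_b * np.exp(mu * dtd.t_grid)
        rho = dtd.rho_tau / (mu * s_grid)
        return SizeAtDivisionDensity(s_b=s_b, s_grid=s_grid, rho_sd=rho, completion=dtd.completion)
    s_grid = np.asarray(s_grid, dtype=float)
    if np.any(s_grid <= 0):
        raise ValueError("size grid must be positive")
    s_max = s_b * math.exp(mu * dtd.t_grid[-1])
    if s_grid.max() > s_max * (1.0 + 1e-9):
        raise ExtrapolationError(
            f"size {s_grid.max():.4g} maps beyond the solved horizon (max size {s_max:.4g})"
        )
    rho = np.zeros_like(s_grid)
    above = s_grid >= s_b
    t_s = np.log(s_grid[above] / s_b) / mu
    rho[above] = _interp_log_density(dtd.t_grid, dtd.rho_tau, t_s) / (mu * s_grid[above])
    return SizeAtDivisionDensity(s_b=s_b, s_grid=s_grid, rho_sd=rho, completion=dtd.completion)


def division_size_density(
    model: DivisionModel,
    growth: GrowthLaw,
    s_b: float,
    s_grid: np.ndarray | None = None,
    **solve_kwargs,
) -> SizeAtDivisionDensity:
    """Convenience pipeline: solve -> rho_tau -> rho_sd for one birth size."""
    stages = solve_stages(model, growth, s_b, **solve_kwargs)
    dtd = division_time_density(stages)
    return size_at_division_density(dtd, s_grid=s_grid)


# --------------------------------------------------------------------------- summaries
def moments(density: SizeAtDivisionDensity, alpha: float) -> float:
    """``<s_d^alpha>`` of a (renormalized) size-at-division density."""
    return density.moment(alpha)


def noise_summary(density: SizeAtDivisionDensity) -> NoiseSummary:
    """Mean added size, its variance and ``CV2_Delta = var(Delta)/<Delta>^2``."""
    m1 = density.moment(1.0)
    m2 = density.moment(2.0)
    mean_added = m1 - density.s_b
    if mean_added <= 0:
        raise DegenerateDensityError(f"mean added size is non-positive ({mean_added:.3g})")
    var_added = m2 - m1 * m1
    return NoiseSummary(mean_added=float(mean_added), var_added=float(var_added), cv2=float(var_added / mean_added**2))


def mean_division_size(model: DivisionModel, growth: GrowthLaw, s_b: float = 1.0, **solve_kwargs) -> float:
    """Predicted conditional mean division size ``<s_d | s_b>``."""
    return division_size_density(model, growth, s_b, **solve_kwargs).moment(1.0)


def strategy_curves(
    model: DivisionModel,
    growth: GrowthLaw,
    s_b_grid: np.ndarray,
    **solve_kwargs,
) -> pd.DataFrame:
    """Theory curves of the division strategy and the noise signature.

    Returns a frame with columns ``s_b``, ``mean_added`` (``<Delta>`` vs s_b,
    the division strategy) and ``cv2`` (``CV2_Delta`` vs s_b, the noise
    signature), one row per entry of ``s_b_grid``.
    """
    s_b_grid = np.asarray(s_b_grid, dtype=float)
    if np.any(s_b_grid <= 0):
        raise ValueError("birth sizes must be positive")
    rows = []
    for s_b in s_b_grid:
        ns = noise_summary(division_size_density(model, growth, float(s_b), **solve_kwargs))
        rows.append((float(s_b), ns.mean_added, ns.cv2))
    return pd.DataFrame(rows, columns=["s_b", "mean_added", "cv2"])
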