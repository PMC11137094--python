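"""Constrained maximum-likelihood fitting and AIC model discrimination.

Each rate-law variant is fitted to normalized ``(s_b, s_d)`` data by maximizing

    logL = sum_i ln rho_sd(s_d_i | s_b_i)

over the integer stage count ``M`` (outer grid with early stopping) and the
variant's continuous shape parameters (inner derivative-free search).  The
rate constant ``k`` is *not* free: at every parameter evaluation it is
re-calibrated so the model's predicted mean division size matches the observed
``<s_d>`` (with ``<s_b> = 1`` after normalization).  Consequently the AIC
parameter counts are: adder 1 (M); degradation 2 (gamma, M); power_law 2
(lam, M); commitment 3 (s0, beta, M).

Models are ranked by ``AIC = 2 n_params - 2 logL``; the relative likelihood of
model i against the AIC-best model is ``p_i = exp[(AIC_min - AIC_i)/2]``, and
models with ``p < 0.05`` are flagged as discarded.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize, minimize_scalar
from scipy.special import gammaln

from ._hazard import commitment_G
from .dataset import Dataset
from .master_equation import (
    LOG_FLOOR,
    DegenerateDensityError,
    IncompleteAbsorptionError,
    division_size_density,
    mean_division_size,
)
from .models import VARIANTS, DivisionModel, GrowthLaw

__all__ = [
    "CalibrationError",
    "FitError",
    "SearchConfig",
    "FitResult",
    "ComparisonTable",
    "calibrate_k",
    "log_likelihood",
    "fit_model",
    "compare_models",
]

#: relative-likelihood threshold below which a model is flagged as discarded
REL_LIKELIHOOD_DISCARD = 0.05

_EVAL_ERRORS = (
    IncompleteAbsorptionError,
    DegenerateDensityError,
    ArithmeticError,
    FloatingPointError,
)


class CalibrationError(RuntimeError):
    """Could not bracket or solve the mean-division-size constraint for k."""


class FitError(RuntimeError):
    """No parameter combination produced a finite likelihood."""


# --------------------------------------------------------------------------- calibration
def calibrate_k(
    model: DivisionModel,
    growth: GrowthLaw,
    target_mean_sd: float,
    *,
    mode: str = "conditional",
    s_b_ref: float = 1.0,
    data: Dataset | None = None,
    k0: float | None = None,
    rtol: float = 1e-6,
    sb_spacing: float = 0.02,
    **solve_kwargs,
) -> float:
    """Rate constant k matching the predicted mean division size to the data.

    ``mode="conditional"`` (default) pins the conditional mean
    ``<s_d | s_b = s_b_ref>`` to ``target_mean_sd`` (the observed ``<s_d>``
    with ``<s_b> = 1``).  ``mode="population"`` instead averages the
    conditional means over the empirical birth-size distribution of ``data``.
    The root is found by bracketing on ``ln k`` (geometric expansion) and
    Brent's method to relative tolerance ``rtol``; the shape parameters and M
    are taken from ``model`` (its k is only used as a bracket seed).
    """
    if mode not in ("conditional", "population"):
        raise ValueError(f"unknown calibration mode {mode!r}")
    if mode == "population" and data is None:
        raise ValueError("population calibration requires data")
    if target_mean_sd <= s_b_ref and mode == "conditional":
        raise CalibrationError(
            f"target mean division size {target_mean_sd} must exceed the reference birth size {s_b_ref}"
        )

    if mode == "conditional":
        def predicted(k: float) -> float:
            return mean_division_size(model.with_k(k), growth, s_b_ref, **solve_kwargs)
    else:
        sb_u, counts = np.unique(_round_sb(data.s_b, sb_spacing), return_counts=True)

        def predicted(k: float) -> float:
            m = model.with_k(k)
            means = [mean_division_size(m, growth, float(sb), **solve_kwargs) for sb in sb_u]
            return float(np.average(means, weights=counts))

    def g(ln_k: float) -> float:
        try:
            return predicted(math.exp(ln_k)) - target_mean_sd
        except IncompleteAbsorptionError:
            # accumulation too slow to absorb: the mean would be enormous
            return float("inf")

    # mean division size decreases monotonically in k; bracket on ln k
    if k0 is None or not (np.isfinite(k0) and k0 > 0):
        k0 = model.M * growth.mu / max(target_mean_sd - s_b_ref, 1e-3)
    lo = hi = math.log(k0)
    g_lo = g_hi = g(lo)
    step = math.log(10.0)
    for _ in range(70):
        if g_lo > 0 and g_hi < 0:
            break
        if g_hi >= 0:
            hi += step
            g_hi = g(hi)
        if g_lo <= 0:
            lo -= step
            g_lo = g(lo)
    else:
        raise CalibrationError(
            f"could not bracket k for {model.variant} (M={model.M}, shape={model.shape_params}, "
            f"target <s_d>={target_mean_sd:.4g})"
        )
    ln_k = brentq(g, lo, hi, xtol=max(rtol / 10.0, 1e-12), rtol=max(rtol, 4e-16))
    return float(math.exp(ln_k))


# --------------------------------------------------------------------------- likelihood
def _round_sb(s_b: np.ndarray, spacing: float) -> np.ndarray:
    return np.maximum(np.round(s_b / spacing) * spacing, spacing)


def _loglik_pointwise(s_b: np.ndarray, s_d: np.ndarray, model: DivisionModel, growth: GrowthLaw) -> np.ndarray:
    """Exact per-record log density for pure-birth variants.

    In the size coordinate the stage count is an inhomogeneous Poisson process
    with per-size hazard ``h(s) = k_+(s)/(mu s)``, so
    ``rho_sd(s_d | s_b) = h(s_d) Lambda^{M-1} e^{-Lambda} / (M-1)!`` with
    ``Lambda`` the cumulative hazard from ``s_b`` to ``s_d``.
    """
    kappa = model.k / growth.mu
    M = model.M
    if model.variant in ("adder", "degradation"):
        Lam = kappa * (s_d - s_b)
    elif model.variant == "power_law":
        lam = model.lam
        Lam = kappa * (s_d**lam - s_b**lam) / lam
    else:
        Lam = kappa * (commitment_G(s_d, model.s0, model.beta) - commitment_G(s_b, model.s0, model.beta))
    Lam = np.maximum(Lam, 0.0)
    hazard = model.rate_up(s_d) / (growth.mu * s_d)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log(hazard) - Lam - gammaln(M)
        if M > 1:
            out = out + (M - 1) * np.log(Lam)
    out = np.where(np.isnan(out), -np.inf, out)
    return np.maximum(out, LOG_FLOOR)


def _loglik_grid(
    s_b: np.ndarray,
    s_d: np.ndarray,
    model: DivisionModel,
    growth: GrowthLaw,
    sb_spacing: float,
    **solve_kwargs,
) -> np.ndarray:
    """Per-record log density via one master-equation solve per rounded s_b."""
    sbr = _round_sb(s_b, sb_spacing)
    uniq, inverse = np.unique(sbr, return_inverse=True)
    out = np.empty_like(s_d)
    mu = growth.mu
    for j, sb in enumerate(uniq):
        sel = inverse == j
        dens = division_size_density(model, growth, float(sb), **solve_kwargs)
        # interpolate the log division-time density; the size density follows
        # by the exact Jacobian 1/(mu s)
        dtd_t = np.log(dens.s_grid / sb) / mu
        with np.errstate(divide="ignore"):
            log_rho_tau = np.maximum(np.log(np.maximum(dens.rho_sd * mu * dens.s_grid, 0.0)), LOG_FLOOR)
        sd_j = s_d[sel]
        t_obs = np.full(sd_j.shape, -1.0)
        ok = sd_j >= sb
        t_obs[ok] = np.log(sd_j[ok] / sb) / mu
        vals = np.interp(t_obs, dtd_t, log_rho_tau, left=LOG_FLOOR, right=LOG_FLOOR)
        vals[ok] = vals[ok] - np.log(mu * sd_j[ok])
        vals[~ok] = LOG_FLOOR
        out[sel] = vals
    return np.maximum(out, LOG_FLOOR)


def log_likelihood(
    data: Dataset,
    model: DivisionModel,
    growth: GrowthLaw,
    *,
    method: str = "auto",
    sb_spacing: float = 0.02,
    **solve_kwargs,
) -> float:
    """Total log-likelihood ``sum_i ln rho_sd(s_d_i | s_b_i)``.

    Birth sizes are first rounded to a grid of ``sb_spacing`` (0.02 normalized
    units by default; far below data noise) for every variant alike, so model
    comparisons are unaffected by the rounding.  ``method="pointwise"`` then
    uses the exact Poisson-counting form (pure-birth variants only);
    ``method="grid"`` runs one master-equation solve per distinct rounded
    birth size and interpolates.  Densities are floored at 1e-300 so the log
    stays finite.  ``sb_spacing=0`` disables rounding.
    """
    if data.N == 0:
        raise ValueError("empty dataset")
    if method == "auto":
        method = "pointwise" if model.is_pure_birth else "grid"
    # every variant conditions on the same rounded birth sizes, so the (tiny)
    # rounding error is shared and cancels out of model comparisons
    s_b = _round_sb(data.s_b, sb_spacing) if sb_spacing else data.s_b
    if method == "pointwise":
        if not model.is_pure_birth:
            raise ValueError("pointwise likelihood requires a pure-birth model")
        vals = _loglik_pointwise(s_b, data.s_d, model, growth)
    elif method == "grid":
        vals = _loglik_grid(s_b, data.s_d, model, growth, sb_spacing or 0.02, **solve_kwargs)
    else:
        raise ValueError(f"unknown likelihood method {method!r}")
    return float(vals.sum())


# --------------------------------------------------------------------------- fitting
@dataclass(frozen=True)
class SearchConfig:
    """Knobs of the maximum-likelihood search (defaults cover the regimes of
    interest with margin; bounds are in normalized units, gamma relative to mu)."""

    m_min: int = 1
    m_max: int = 40
    #: coarse rungs of the integer-M search; the best rung is refined locally
    m_ladder: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 8, 10, 13, 16, 20, 25, 31, 40)
    early_stop: int = 5  # consecutive non-improving ladder rungs before stopping
    gamma_over_mu_bounds: tuple[float, float] = (0.0, 20.0)
    lam_bounds: tuple[float, float] = (0.2, 8.0)
    s0_bounds: tuple[float, float] = (0.1, 5.0)
    beta_bounds: tuple[float, float] = (0.0, 100.0)
    gamma_over_mu_grid: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0)
    lam_grid: tuple[float, ...] = (0.2, 0.5, 1.0, 1.5, 2.0, 3.0, 4.5, 6.0, 8.0)
    s0_grid: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 3.0)
    beta_grid: tuple[float, ...] = (1.0, 3.0, 8.0, 20.0, 50.0)
    scalar_xatol: float = 5e-3
    nm_maxfev: int = 50
    calibration: str = "conditional"
    sb_spacing: float = 0.02
    fixed: dict = field(default_factory=dict)  # pin shape params, e.g. {"lam": 1.0}


@dataclass
class FitResult:
    """Best-fit summary of one variant on one dataset."""

    variant: str
    model: DivisionModel  # fitted shape parameters with the calibrated k
    logL: float
    n_params: int
    aic: float
    n_obs: int
    delta_aic: float | None = None
    rel_likelihood: float | None = None
    discarded: bool | None = None

    @property
    def params(self) -> dict[str, float]:
        out: dict[str, float] = {"M": self.model.M}
        out.update(self.model.shape_params)
        return out

    @property
    def k(self) -> float:
        return self.model.k


@dataclass
class ComparisonTable:
    """All four variants fitted to one dataset, ranked by AIC."""

    fits: list[FitResult]
    failures: dict[str, str] = field(default_factory=dict)
    label: str = ""

    @property
    def best(self) -> FitResult:
        return self.fits[0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.fits:
            row: dict = {"variant": f.variant, "M": f.model.M}
            for name in ("gamma", "lam", "s0", "beta"):
                row[name] = getattr(f.model, name)
            row.update(
                k=f.k,
                logL=f.logL,
                n_params=f.n_params,
                aic=f.aic,
                delta_aic=f.delta_aic,
                rel_likelihood=f.rel_likelihood,
                discarded=f.discarded,
            )
            rows.append(row)
        return pd.DataFrame(rows)


def _maximize_1d(f: Callable[[float], float], grid: Iterable[float], bounds: tuple[float, float], xatol: float):
    """Coarse grid scan followed by bounded Brent refinement; returns (x, f(x))."""
    pts = sorted({float(x) for x in grid if bounds[0] <= x <= bounds[1]} | set(map(float, bounds)))
    vals = [f(x) for x in pts]
    i = int(np.argmax(vals))
    best_x, best_v = pts[i], vals[i]
    lo = pts[max(i - 1, 0)]
    hi = pts[min(i + 1, len(pts) - 1)]
    if hi > lo:
        res = minimize_scalar(lambda x: -f(x), bounds=(lo, hi), method="bounded", options={"xatol": xatol, "maxiter": 40})
        if np.isfinite(res.fun) and -res.fun > best_v:
            best_x, best_v = float(res.x), float(-res.fun)
    return best_x, best_v


def fit_model(
    data: Dataset,
    variant: str,
    growth: GrowthLaw | None = None,
    config: SearchConfig | None = None,
) -> FitResult:
    """Maximum-likelihood fit of one variant with k calibrated at every step.

    Outer search over the integer stage count M: a coarse ascending ladder
    (stopping after ``early_stop`` consecutive rungs without improvement,
    since the profile likelihood in M is unimodal in practice) followed by
    local refinement around the best rung.  Inner derivative-free search over
    the variant's continuous shape parameters.  The endpoint at which the
    variant degenerates to the adder (gamma=0, lam=1, beta=0) is always
    evaluated, so nesting consistency holds by construction.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    growth = growth or GrowthLaw()
    cfg = config or SearchConfig()
    target = data.mean_sd
    mu = growth.mu
    warm_k: dict[int, float] = {}
    m_best: dict[int, float] = {}

    best: tuple[float, DivisionModel | None] = (-np.inf, None)

    def evaluate(M: int, shape: dict[str, float]) -> float:
        nonlocal best
        try:
            seed_k = warm_k.get(M, M * mu / max(target - 1.0, 1e-3))
            trial = DivisionModel(variant=variant, k=seed_k, M=M, **shape)
            k_hat = calibrate_k(
                trial, growth, target,
                mode=cfg.calibration, data=data, k0=seed_k, sb_spacing=cfg.sb_spacing,
            )
            fitted = trial.with_k(k_hat)
            ll = log_likelihood(data, fitted, growth, sb_spacing=cfg.sb_spacing)
        except (CalibrationError, *_EVAL_ERRORS):
            return -np.inf
        warm_k[M] = k_hat
        m_best[M] = max(m_best.get(M, -np.inf), ll)
        if ll > best[0]:
            best = (ll, fitted)
        return ll

    fixed = dict(cfg.fixed)
    prev_shape: dict[str, float] | None = None

    def search_M(M: int) -> None:
        nonlocal prev_shape
        m_best.setdefault(M, -np.inf)
        if variant == "adder":
            evaluate(M, {})
        elif variant == "degradation":
            if "gamma" in fixed:
                evaluate(M, {"gamma": float(fixed["gamma"])})
            else:
                g_bounds = (cfg.gamma_over_mu_bounds[0] * mu, cfg.gamma_over_mu_bounds[1] * mu)
                grid = [g * mu for g in cfg.gamma_over_mu_grid]
                if prev_shape:
                    grid.append(prev_shape["gamma"])
                x, _ = _maximize_1d(lambda g: evaluate(M, {"gamma": g}), grid, g_bounds, cfg.scalar_xatol * mu)
                prev_shape = {"gamma": x}
        elif variant == "power_law":
            if "lam" in fixed:
                evaluate(M, {"lam": float(fixed["lam"])})
            else:
                grid = list(cfg.lam_grid)
                if prev_shape:
                    grid.append(prev_shape["lam"])
                x, _ = _maximize_1d(lambda l: evaluate(M, {"lam": l}), grid, cfg.lam_bounds, cfg.scalar_xatol)
                prev_shape = {"lam": x}
        else:  # commitment
            if "beta" in fixed or "s0" in fixed:
                shape = {"s0": float(fixed.get("s0", 1.0)), "beta": float(fixed.get("beta", 0.0))}
                evaluate(M, shape)
            else:
                evaluate(M, {"s0": 1.0, "beta": 0.0})  # adder-reduction endpoint
                coarse = [(s0, b) for s0 in cfg.s0_grid for b in cfg.beta_grid]
                cv = [evaluate(M, {"s0": s0, "beta": b}) for s0, b in coarse]
                starts = [coarse[int(np.argmax(cv))]]
                if prev_shape:
                    starts.append((prev_shape["s0"], prev_shape["beta"]))
                for x0 in starts:
                    minimize(
                        lambda x: -evaluate(M, {"s0": float(x[0]), "beta": float(x[1])}),
                        x0=np.asarray(x0, dtype=float),
                        method="Nelder-Mead",
                        bounds=[cfg.s0_bounds, cfg.beta_bounds],
                        options={"maxfev": cfg.nm_maxfev, "xatol": 1e-2, "fatol": 1e-3},
                    )
                if best[1] is not None and best[1].variant == "commitment" and best[1].beta > 0:
                    prev_shape = {"s0": best[1].s0, "beta": best[1].beta}

    ladder = [M for M in cfg.m_ladder if cfg.m_min <= M <= cfg.m_max]
    if not ladder:
        ladder = list(range(cfg.m_min, cfg.m_max + 1))
    since_improve = 0
    for M in ladder:
        before = best[0]
        search_M(M)
        if best[0] > before:
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= cfg.early_stop:
                break
    # refine the integer M locally around the best rung until it is interior
    while np.isfinite(best[0]):
        M_star = max(m_best, key=m_best.get)
        candidates = [
            M
            for M in (M_star - 1, M_star + 1, M_star - 2, M_star + 2)
            if cfg.m_min <= M <= cfg.m_max and M not in m_best
        ]
        if not candidates:
            break
        for M in candidates:
            search_M(M)

    ll, model = best
    if model is None or not np.isfinite(ll):
        raise FitError(
            f"no finite likelihood found for variant {variant!r} (N={data.N}, target <s_d>={target:.4g})"
        )
    n_params = model.n_params
    aic = 2.0 * n_params - 2.0 * ll
    return FitResult(variant=variant, model=model, logL=ll, n_params=n_params, aic=aic, n_obs=data.N)


def compare_models(
    data: Dataset,
    growth: GrowthLaw | None = None,
    config: SearchConfig | None = None,
    variants: Iterable[str] = VARIANTS,
) -> ComparisonTable:
    """Fit every variant, rank by AIC and attach relative likelihoods.

    AIC ties break toward fewer parameters (parsimony).  Per-variant fit
    failures are recorded and the comparison proceeds on the remaining models;
    models with relative likelihood below 0.05 are flagged as discarded.
    """
    growth = growth or GrowthLaw()
    fits: list[FitResult] = []
    failures: dict[str, str] = {}
    for variant in variants:
        try:
            fits.append(fit_model(data, variant, growth, config))
        except (FitError, CalibrationError) as exc:
            failures[variant] = str(exc)
    if not fits:
        raise FitError(f"all variants failed to fit: {failures}")
    fits.sort(key=lambda f: (f.aic, f.n_params))
    aic_min = fits[0].aic
    for f in fits:
        f.delta_aic = f.aic - aic_min
        f.rel_likelihood = min(math.exp((aic_min - f.aic) / 2.0), 1.0)
        f.discarded = f.rel_likelihood < REL_LIKELIHOOD_DISCARD
    return ComparisonTable(fits=fits, failures=failures, label=data.label)
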