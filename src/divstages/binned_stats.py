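"""Quantile-binned division strategy, noise signature, and bootstrap CIs.

The division strategy (``<Delta>`` vs ``s_b``) and noise signature
(``CV2_Delta`` vs ``s_b``) are estimated from data by quantile splitting:
cycles are sorted by birth size and partitioned into equal-count bins (five by
default), and the per-bin statistics are the conditional moments.  Error bars
are percentile-bootstrap 95% confidence intervals.  The within-bin noise is
the within-bin variance of the added size over the squared within-bin mean,
consistent with the conditional definition ``CV2 = var(Delta)/<Delta>^2``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import Dataset

__all__ = [
    "QuantileBin",
    "CorrelationResult",
    "quantile_split",
    "bootstrap_ci",
    "delta_sb_correlation",
    "bins_to_frame",
    "plot_strategy_and_noise",
]


@dataclass(frozen=True)
class QuantileBin:
    """Conditional statistics of one birth-size quantile."""

    q: int
    n_q: int
    mean_sb: float
    mean_delta: float
    cv2_delta: float
    mean_sb_ci: tuple[float, float]
    mean_delta_ci: tuple[float, float]
    cv2_delta_ci: tuple[float, float]


@dataclass(frozen=True)
class CorrelationResult:
    """Delta-vs-s_b correlation with a bootstrap confidence interval."""

    r: float
    ci_low: float
    ci_high: float
    method: str
    n_boot: int

    @property
    def adder_compatible(self) -> bool:
        """True when the CI includes zero (no detectable size dependence)."""
        return self.ci_low <= 0.0 <= self.ci_high


def _bin_slices(n: int, n_bins: int) -> list[slice]:
    """Equal-count partition; the remainder is spread from the lowest bin up."""
    base, rem = divmod(n, n_bins)
    sizes = [base + 1 if i < rem else base for i in range(n_bins)]
    edges = np.concatenate([[0], np.cumsum(sizes)])
    return [slice(int(edges[i]), int(edges[i + 1])) for i in range(n_bins)]


def _cv2(delta: np.ndarray) -> float:
    m = delta.mean()
    return float(delta.var() / m**2)


def bootstrap_ci(
    values: np.ndarray,
    statistic: Callable = np.mean,
    n_boot: int = 1000,
    level: float = 0.95,
    rng=None,
) -> tuple[float, float]:
    """Percentile bootstrap interval for ``statistic`` of a 1-D sample."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("bootstrap requires a non-empty sample")
    rng = np.random.default_rng(rng)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    resampled = values[idx]
    try:
        est = np.asarray(statistic(resampled, axis=1), dtype=float)
    except TypeError:
        est = np.array([statistic(row) for row in resampled], dtype=float)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(est, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def quantile_split(
    data: Dataset,
    n_quantiles: int = 5,
    *,
    n_boot: int = 1000,
    level: float = 0.95,
    rng=0,
) -> list[QuantileBin]:
    """Split cycles into equal-count birth-size bins and summarize each.

    Ties in ``s_b`` are broken by stable sort order for determinism, and so is
    the default bootstrap stream (``rng=0``).
    """
    if data.N < n_quantiles:
        raise ValueError(f"need at least {n_quantiles} records, got {data.N}")
    rng = np.random.default_rng(rng)
    order = np.argsort(data.s_b, kind="stable")
    sb = data.s_b[order]
    delta = data.delta[order]
    bins: list[QuantileBin] = []
    for q, sl in enumerate(_bin_slices(data.N, n_quantiles)):
        sb_q, d_q = sb[sl], delta[sl]
        bins.append(
            QuantileBin(
                q=q,
                n_q=sb_q.size,
                mean_sb=float(sb_q.mean()),
                mean_delta=float(d_q.mean()),
                cv2_delta=_cv2(d_q),
                mean_sb_ci=bootstrap_ci(sb_q, np.mean, n_boot, level, rng),
                mean_delta_ci=bootstrap_ci(d_q, np.mean, n_boot, level, rng),
                cv2_delta_ci=bootstrap_ci(d_q, lambda x, axis=None: (
                    np.var(x, axis=axis) / np.mean(x, axis=axis) ** 2
                ), n_boot, level, rng),
            )
        )
    return bins


def delta_sb_correlation(
    data: Dataset,
    rng=0,
    *,
    n_boot: int = 1000,
    level: float = 0.95,
    method: str = "pearson",
) -> CorrelationResult:
    """Correlation between added size and birth size, with a bootstrap CI.

    The CI including zero is the adder-compatibility criterion; increasingly
    negative correlations mark increasingly sizer-like conditions.
    """
    if data.N < 3:
        raise ValueError("correlation requires at least 3 records")
    if np.ptp(data.s_b) == 0:
        raise ValueError("correlation undefined: zero variance in s_b")
    rng = np.random.default_rng(rng)
    corr = {"pearson": stats.pearsonr, "spearman": stats.spearmanr}[method]
    r = float(corr(data.s_b, data.delta).statistic)
    idx = rng.integers(0, data.N, size=(n_boot, data.N))
    sb_r, d_r = data.s_b[idx], data.delta[idx]
    if method == "pearson":
        sb_c = sb_r - sb_r.mean(axis=1, keepdims=True)
        d_c = d_r - d_r.mean(axis=1, keepdims=True)
        denom = np.sqrt((sb_c**2).sum(axis=1) * (d_c**2).sum(axis=1))
        boot = np.divide((sb_c * d_c).sum(axis=1), denom, out=np.zeros(n_boot), where=denom > 0)
    else:
        boot = np.array([corr(a, b).statistic for a, b in zip(sb_r, d_r)])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    return CorrelationResult(r=r, ci_low=float(lo), ci_high=float(hi), method=method, n_boot=n_boot)


def bins_to_frame(bins: Sequence[QuantileBin]) -> pd.DataFrame:
    """Flat CSV-friendly table of quantile-bin statistics."""
    return pd.DataFrame(
        {
            "quantile": [b.q for b in bins],
            "n": [b.n_q for b in bins],
            "mean_sb": [b.mean_sb for b in bins],
            "mean_sb_lo": [b.mean_sb_ci[0] for b in bins],
            "mean_sb_hi": [b.mean_sb_ci[1] for b in bins],
            "mean_delta": [b.mean_delta for b in bins],
            "mean_delta_lo": [b.mean_delta_ci[0] for b in bins],
            "mean_delta_hi": [b.mean_delta_ci[1] for b in bins],
            "cv2_delta": [b.cv2_delta for b in bins],
            "cv2_delta_lo": [b.cv2_delta_ci[0] for b in bins],
            "cv2_delta_hi": [b.cv2_delta_ci[1] for b in bins],
        }
    )


def plot_strategy_and_noise(
    bins: Sequence[QuantileBin] | None = None,
    curves: pd.DataFrame | None = None,
    axes=None,
    label: str = "",
):
    """Two-panel figure: division strategy (top) and noise signature (bottom).

    ``bins`` are drawn as points with bootstrap error bars, ``curves`` (the
    output of :func:`divstages.master_equation.strategy_curves`) as lines.
    """
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(2, 1, sharex=True, figsize=(4.5, 6))
    ax_top, ax_bot = axes
    if curves is not None:
        ax_top.plot(curves["s_b"], curves["mean_added"], "-", label=label or "theory")
        ax_bot.plot(curves["s_b"], curves["cv2"], "-", label=label or "theory")
    if bins is not None:
        sb = [b.mean_sb for b in bins]
        md = [b.mean_delta for b in bins]
        cv = [b.cv2_delta for b in bins]
        md_err = [[b.mean_delta - b.mean_delta_ci[0] for b in bins], [b.mean_delta_ci[1] - b.mean_delta for b in bins]]
        cv_err = [[b.cv2_delta - b.cv2_delta_ci[0] for b in bins], [b.cv2_delta_ci[1] - b.cv2_delta for b in bins]]
        ax_top.errorbar(sb, md, yerr=np.abs(md_err), fmt="o", capsize=3, label=label or "data")
        ax_bot.errorbar(sb, cv, yerr=np.abs(cv_err), fmt="o", capsize=3, label=label or "data")
    ax_top.set_ylabel(r"$\langle\Delta\rangle$")
    ax_bot.set_ylabel(r"$CV^2_\Delta$")
    ax_bot.set_xlabel(r"$s_b$ (units of $\langle s_b\rangle$)")
    return axes
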