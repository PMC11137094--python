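"""Growth law and division-rate laws for multistage cell-division models.

A cell cycle is modelled as exponential single-cell growth, ``s(t) = s_b e^{mu t}``,
during which abstract *division stages* (interpretable as accumulated precursor
protein, e.g. FtsZ) are completed stochastically.  Division fires when the stage
count first reaches ``M``.  The four rate laws differ in how the stage gain rate
``k_+`` depends on the current size ``s`` and whether stages can be lost (rate
``k_-``):

========== ============================== ==============
variant    k_+(s)                         k_-(m)
========== ============================== ==============
adder        k s                           0
degradation  k s                           gamma m
power_law    k s**lam                      0
commitment   k s / (1 + (s0/s)**beta)      0
========== ============================== ==============

The rate constant ``k`` is never a free parameter of a fit: it is pinned by a
calibration constraint on the mean division size (see :mod:`divstages.inference`).
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np

__all__ = ["GrowthLaw", "DivisionModel", "VARIANTS"]

VARIANTS = ("adder", "degradation", "power_law", "commitment")

#: continuous shape parameters (besides the integer stage count M) per variant
SHAPE_FIELDS: dict[str, tuple[str, ...]] = {
    "adder": (),
    "degradation": ("gamma",),
    "power_law": ("lam",),
    "commitment": ("s0", "beta"),
}

#: number of free parameters counted by the AIC: M plus the shape parameters.
#: The calibrated rate constant k is excluded (it is fixed by the constraint
#: on the mean division size, not fitted).
N_PARAMS: dict[str, int] = {v: 1 + len(f) for v, f in SHAPE_FIELDS.items()}


@dataclass(frozen=True)
class GrowthLaw:
    """Exponential single-cell growth ``ds/dt = mu s``.

    Parameters
    ----------
    mu : float
        Growth rate (inverse time).  Defaults to ``ln 2`` so that time is
        measured in mean doubling times.
    """

    mu: float = math.log(2.0)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mu) and self.mu > 0):
            raise ValueError(f"growth rate mu must be positive and finite, got {self.mu}")

    @property
    def doubling_time(self) -> float:
        return math.log(2.0) / self.mu

    def size_at(self, s_b, t):
        """Size after time ``t`` from birth at size ``s_b``: ``s_b e^{mu t}``."""
        s_b_a = np.asarray(s_b, dtype=float)
        t_a = np.asarray(t, dtype=float)
        if np.any(s_b_a <= 0):
            raise ValueError("birth size s_b must be positive")
        if np.any(t_a < 0):
            raise ValueError("time since birth must be non-negative")
        out = s_b_a * np.exp(self.mu * t_a)
        return float(out) if out.ndim == 0 else out

    def time_at(self, s, s_b):
        """Inverse of :meth:`size_at`: time at which size ``s`` is reached."""
        s_a = np.asarray(s, dtype=float)
        s_b_a = np.asarray(s_b, dtype=float)
        if np.any(s_a <= 0) or np.any(s_b_a <= 0):
            raise ValueError("sizes must be positive")
        out = np.log(s_a / s_b_a) / self.mu
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DivisionModel:
    """One of the four division-rate laws with its parameters.

    Construct through the variant-specific classmethods
    (:meth:`adder`, :meth:`degradation`, :meth:`power_law`, :meth:`commitment`),
    which only accept the parameters their variant uses.  Supplying a parameter
    a variant does not use raises, so that AIC parameter counting stays
    unambiguous.
    """

    variant: str
    k: float
    M: int
    gamma: float | None = None  # per-stage degradation rate (degradation only)
    lam: float | None = None    # size exponent (power_law only)
    s0: float | None = None     # commitment size (commitment only)
    beta: float | None = None   # Hill exponent (commitment only)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if not (np.isfinite(self.k) and self.k > 0):
            raise ValueError(f"rate constant k must be positive, got {self.k}")
        if not (isinstance(self.M, (int, np.integer)) and self.M >= 1):
            raise ValueError(f"stage count M must be an integer >= 1, got {self.M!r}")
        object.__setattr__(self, "M", int(self.M))
        needed = SHAPE_FIELDS[self.variant]
        for name in ("gamma", "lam", "s0", "beta"):
            value = getattr(self, name)
            if name in needed:
                if value is None:
                    raise ValueError(f"variant {self.variant!r} requires parameter {name!r}")
            elif value is not None:
                raise ValueError(
                    f"variant {self.variant!r} does not take parameter {name!r} "
                    "(extraneous parameters would corrupt AIC parameter counting)"
                )
        if self.gamma is not None and self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.lam is not None and self.lam <= 0:
            raise ValueError("lam must be > 0")
        if self.s0 is not None and self.s0 <= 0:
            raise ValueError("s0 must be > 0")
        if self.beta is not None and self.beta < 0:
            raise ValueError("beta must be >= 0")

    # ------------------------------------------------------------------ construction
    @classmethod
    def adder(cls, k: float, M: int) -> "DivisionModel":
        return cls(variant="adder", k=k, M=M)

    @classmethod
    def degradation(cls, k: float, M: int, gamma: float) -> "DivisionModel":
        return cls(variant="degradation", k=k, M=M, gamma=gamma)

    @classmethod
    def power_law(cls, k: float, M: int, lam: float) -> "DivisionModel":
        return cls(variant="power_law", k=k, M=M, lam=lam)

    @classmethod
    def commitment(cls, k: float, M: int, s0: float, beta: float) -> "DivisionModel":
        return cls(variant="commitment", k=k, M=M, s0=s0, beta=beta)

    # ------------------------------------------------------------------ properties
    @property
    def n_params(self) -> int:
        """Free parameters counted by the AIC (k excluded)."""
        return N_PARAMS[self.variant]

    @property
    def shape_params(self) -> dict[str, float]:
        """The continuous non-k parameters of this variant."""
        return {name: float(getattr(self, name)) for name in SHAPE_FIELDS[self.variant]}

    @property
    def is_pure_birth(self) -> bool:
        """True when stages can only accumulate (k_-(m) = 0 for every m)."""
        return self.variant != "degradation" or self.gamma == 0.0

    def with_k(self, k: float) -> "DivisionModel":
        return dataclasses.replace(self, k=float(k))

    # ------------------------------------------------------------------ rates
    def rate_up(self, s):
        """Stage gain rate ``k_+(s)`` at cell size ``s`` (scalar or array)."""
        s_a = np.asarray(s, dtype=float)
        if np.any(s_a <= 0):
            raise ValueError("cell size must be positive")
        if self.variant in ("adder", "degradation"):
            out = self.k * s_a
        elif self.variant == "power_law":
            out = self.k * s_a**self.lam
        else:  # commitment: Hill gate suppresses accumulation below s0
            with np.errstate(over="ignore"):
                hill = (self.s0 / s_a) ** self.beta
            out = self.k * s_a / (1.0 + hill)
        return float(out) if out.ndim == 0 else out

    def rate_down(self, m):
        """Stage loss rate ``k_-(m)`` with ``m`` stages present (scalar or array)."""
        m_a = np.asarray(m, dtype=float)
        if np.any(m_a < 0) or np.any(m_a > self.M):
            raise ValueError(f"stage count m must lie in [0, {self.M}]")
        if self.variant == "degradation":
            out = self.gamma * m_a
        else:
            out = np.zeros_like(m_a)
        return float(out) if out.ndim == 0 else out

    # ------------------------------------------------------------------ config round-trip
    def to_config(self) -> dict[str, Any]:
        """Flat mapping (variant name + parameter values), YAML/JSON friendly."""
        cfg: dict[str, Any] = {"variant": self.variant, "k": float(self.k), "M": int(self.M)}
        cfg.update(self.shape_params)
        return cfg

    @classmethod
    def from_config(cls, cfg: Mapping[str, Any]) -> "DivisionModel":
        cfg = dict(cfg)
        variant = cfg.pop("variant")
        return cls(variant=variant, k=float(cfg.pop("k")), M=int(cfg.pop("M")), **cfg)
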