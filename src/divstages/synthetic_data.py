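"""Mother-machine-like synthetic condition datasets with known ground truth.

Each condition emulates a long single-cell lineage in a mother machine:
exponential growth at fixed mu, division after M stochastic stage events under
a chosen rate law, exactly symmetric halving, optional multiplicative
log-normal measurement noise on the recorded lengths, and normalization by the
empirical mean birth size.  The generating model is attached as metadata so
recovery of the ground truth by the fitting pipeline can be tested end to end.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import Dataset
from .inference import calibrate_k
from .models import DivisionModel, GrowthLaw
from .simulator import lineage_rng, records_to_arrays, simulate_lineage

__all__ = ["ConditionSpec", "generate_condition", "generate_benchmark_suite"]


@dataclass(frozen=True)
class ConditionSpec:
    """Recipe for one synthetic growth condition."""

    label: str
    model: DivisionModel
    growth: GrowthLaw = field(default_factory=GrowthLaw)
    n_cycles: int = 10000
    seed: int = 0
    noise_sd: float = 0.0  # sd of log measurement noise on recorded lengths
    burn_in: int = 50
    s_b0: float = 1.0

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_condition(spec: ConditionSpec) -> Dataset:
    """Simulate one lineage and package it as a normalized Dataset."""
    rng = lineage_rng(spec.seed, 0)
    records = simulate_lineage(
        spec.model, spec.growth, s_b0=spec.s_b0, n_cycles=spec.n_cycles, burn_in=spec.burn_in, rng=rng
    )
    s_b, s_d, tau = records_to_arrays(records)
    if spec.noise_sd > 0:
        s_b = s_b * np.exp(spec.noise_sd * rng.standard_normal(s_b.size))
        s_d = s_d * np.exp(spec.noise_sd * rng.standard_normal(s_d.size))
    return Dataset.from_raw(
        s_b,
        s_d,
        tau=tau,
        label=spec.label,
        meta={
            "ground_truth": spec.model.to_config(),
            "mu": spec.growth.mu,
            "seed": spec.seed,
            "noise_sd": spec.noise_sd,
            "n_cycles": spec.n_cycles,
        },
    )


def _benchmark_specs(growth: GrowthLaw, M: int = 10) -> list[tuple[str, str, dict]]:
    # variant, label, shape params; weak/strong pairs span the sizer-like regimes
    return [
        ("adder", "adder", {}),
        ("degradation", "degradation_weak", {"gamma": 0.5 * growth.mu}),
        ("degradation", "degradation_strong", {"gamma": 2.0 * growth.mu}),
        ("power_law", "power_law_weak", {"lam": 2.0}),
        ("power_law", "power_law_strong", {"lam": 4.0}),
        ("commitment", "commitment_weak", {"s0": 1.5, "beta": 4.0}),
        ("commitment", "commitment_strong", {"s0": 2.5, "beta": 20.0}),
    ]


def generate_benchmark_suite(
    seed: int = 0,
    n_cycles: int = 5000,
    growth: GrowthLaw | None = None,
    M: int = 10,
    noise_sd: float = 0.0,
) -> dict[str, Dataset]:
    """One dataset per rate-law regime, with k calibrated so ``<Delta> = 1``.

    Every generating model uses M = 10 stages and has its rate constant set so
    the predicted mean division size at ``s_b = 1`` is 2 (mean added size equal
    to the mean birth size, the standard normalization).  Labels carry the
    regime; the generating parameters ride along in ``Dataset.meta``.
    """
    growth = growth or GrowthLaw()
    child_seeds = np.random.SeedSequence(seed).generate_state(16) & 0x7FFFFFFF
    out: dict[str, Dataset] = {}
    for i, (variant, label, shape) in enumerate(_benchmark_specs(growth, M)):
        model = DivisionModel(variant=variant, k=1.0, M=M, **shape)
        k = calibrate_k(model, growth, target_mean_sd=2.0)
        spec = ConditionSpec(
            label=label,
            model=model.with_k(k),
            growth=growth,
            n_cycles=n_cycles,
            seed=int(child_seeds[i]),
            noise_sd=noise_sd,
        )
        out[label] = generate_condition(spec)
    return out
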