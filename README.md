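# divstages

Multistage stochastic models of bacterial cell-size control: master-equation
solvers, exact lineage simulation, and AIC-based discrimination between
division mechanisms.

## The problem

Under fast growth, *E. coli* and other rod-shaped bacteria divide by the
**adder** rule: the size added between birth and division,
`Delta = s_d - s_b`, is uncorrelated with the size at birth `s_b`.  Under
slow growth the strategy becomes **sizer-like** — `Delta` decreases with
`s_b` — and several molecular mechanisms can produce that deviation.  This
package implements a family of multistage division models that nest the
competing mechanisms, and a likelihood pipeline that asks the data which
mechanism explains them best.

Division is modelled as the completion of `M` stochastic stages (e.g.
accumulation of a precursor protein such as FtsZ) while the cell grows
exponentially, `ds/dt = mu s`.  The stage gain rate `k_+(s)` and loss rate
`k_-(m)` define the variants:

| variant     | `k_+(s)`                  | `k_-(m)`  | mechanism |
|-------------|---------------------------|-----------|-----------|
| adder       | `k s`                     | 0         | size-proportional accumulation |
| degradation | `k s`                     | `gamma m` | precursor degradation |
| power_law   | `k s^lambda`              | 0         | superlinear size dependence |
| commitment  | `k s / (1 + (s0/s)^beta)` | 0         | accumulation gated above a commitment size `s0` |

From the master equation for the stage probabilities `P_m(t)` the package
derives the division-time density `rho_tau = k_+ P_{M-1}`, the conditional
size-at-division density `rho(s_d | s_b)`, the division strategy
`<Delta>(s_b)` and the noise signature `CV2_Delta(s_b)`.  Each variant is fit
to `(s_b, s_d)` data by maximum likelihood — with the rate constant `k`
pinned so the predicted mean division size matches the observed one — and
the variants are ranked by `AIC = 2 n_params - 2 logL` with relative
likelihood `p = exp[(AIC_min - AIC_i)/2]`.

See `docs/methods.md` for the numerical methods and design choices.

## Worked example

Generate a synthetic mother-machine condition with a strongly sizer-like
ground truth (power-law accumulation, `lambda = 4`, `M = 10`), then ask the
pipeline which mechanism generated it:

```python
import numpy as np
from divstages import (GrowthLaw, DivisionModel, ConditionSpec, generate_condition,
                       calibrate_k, delta_sb_correlation, compare_models)

growth = GrowthLaw()  # mu = ln 2: time in mean doubling times
truth = DivisionModel.power_law(k=1.0, M=10, lam=4.0)
truth = truth.with_k(calibrate_k(truth, growth, target_mean_sd=2.0))

data = generate_condition(ConditionSpec(label="strong-power-law", model=truth,
                                        n_cycles=5000, seed=7))
corr = delta_sb_correlation(data, rng=0)
print(f"corr(Delta, s_b) = {corr.r:+.3f}  95% CI [{corr.ci_low:+.3f}, {corr.ci_high:+.3f}]")

table = compare_models(data, growth)   # fits all four variants, ~1 min
print(table.to_frame()[["variant", "M", "gamma", "lam", "s0", "beta",
                        "logL", "aic", "rel_likelihood"]].round(3).to_string(index=False))
```

Output:

```
corr(Delta, s_b) = -0.375  95% CI [-0.398, -0.351]
    variant  M  gamma   lam  s0  beta     logL       aic  rel_likelihood
  power_law 12    NaN 3.572 NaN   NaN 2434.387 -4864.773           1.000
 commitment 12    NaN   NaN 3.0   3.0 2431.805 -4857.611           0.028
degradation 40  0.359   NaN NaN   NaN 2056.732 -4109.463           0.000
      adder 38    NaN   NaN NaN   NaN 2011.355 -4020.711           0.000
```

The negative correlation with a CI excluding zero marks the condition as
sizer-like, and the AIC ranking recovers the generating mechanism: the
power-law model wins (`lambda_hat = 3.6` against a ground truth of 4.0,
`M_hat = 12` against 10), the three-parameter commitment model comes second
but falls below the 0.05 relative-likelihood line, and the adder and
degradation models are decisively rejected.

A command-line interface wraps the same pipeline
(`divstages simulate | theory | fit | compare | stats`); real datasets load
from CSV with columns `size_at_birth, size_at_division` (any length units —
lengths are normalized by the mean birth size), with a `--column-mapping`
escape hatch in the library API for differently named columns.

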