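# Methods

## Model

A bacterial cell cycle is described by two coupled processes:

1. **Deterministic growth.** Cell size (length) grows exponentially,
   `ds/dt = mu s`, so `s(t) = s_b exp(mu t)` from birth size `s_b`.  The
   growth rate defaults to `mu = ln 2`, which makes time dimensionless in
   units of the mean doubling time.  `mu` is constant within a condition:
   per-cell growth-rate variability is out of scope.
2. **Stochastic division stages.** Division is triggered when an abstract
   stage counter `m` (interpretable as accumulated precursor protein such as
   FtsZ) first reaches a target `M`.  Stages accumulate at a size-dependent
   rate `k_+(s)` and, in one variant, are lost at a state-dependent rate
   `k_-(m)`.

The four rate laws, each reducing to the adder in the indicated limit:

| variant     | `k_+(s)`                   | `k_-(m)`  | adder limit |
|-------------|----------------------------|-----------|-------------|
| adder       | `k s`                      | 0         | —           |
| degradation | `k s`                      | `gamma m` | `gamma -> 0`|
| power_law   | `k s^lambda`               | 0         | `lambda = 1`|
| commitment  | `k s / (1 + (s0/s)^beta)`  | 0         | `beta -> 0` (after rate calibration; at `beta = 0` the Hill gate is exactly 1/2, i.e. an adder with `k/2`) |

The stage probabilities `P_m(t)` given `s_b` obey an (M+1)-state forward
Kolmogorov (master) equation with `P_m(0) = delta_{m,0}`; the top state is
absorbing, so `P_M(t)` is the CDF of the division time and
`rho_tau = k_+ P_{M-1}` its density (computed from this identity, never by
differencing `P_M`).  The change of variables `s = s_b exp(mu t)` yields the
conditional size-at-division density `rho(s_d | s_b) = rho_tau(t(s_d))/(mu s_d)`,
whose first two moments give the division strategy `<Delta>(s_b)` and the
noise signature `CV2_Delta(s_b) = var(Delta)/<Delta>^2`.

## Solver

*Pure-birth variants* (`k_- = 0`): the stage counter is an inhomogeneous
Poisson counting process, so the master equation has the exact solution
`P_m(t) = Pois(m; Lambda(t))` for `m < M`, with `Lambda` the cumulative
hazard obtained by trapezoidal quadrature of `k_+` along the growth path.
This is the default ("analytic") path; a scipy LSODA integration of the same
equation (`method="ode"`, rtol 1e-8/atol 1e-12) is kept as an independent
cross-check and the two agree to ~1e-6 in the CDF.

*Degradation*: no closed solution exists, and model fitting needs ~1e4
solves, so the primary path is a classical RK4 integrator with adaptive
substepping (substep length bounded by `0.05 / max total rate`), jitted with
numba and frozen once `P_M > 1 - 1e-12`.  It matches LSODA to better than
1e-5 in every state occupancy and is used only after that agreement is
established by the test suite.  Without numba the LSODA path is used
transparently.

*Horizon*: integration starts at 10 mean doubling times and doubles until
`P_M` reaches `1 - 1e-6` (cap: 80 doubling times, then an
incomplete-absorption error reporting the mass reached).  A second pass
re-solves on a grid trimmed to the absorption time (plus 5%), so narrow
division windows — e.g. the near-sizer commitment regime, where the
division-size distribution has width ~`s*/ (beta sqrt(M))` — stay resolved.
Default output grids: 4000 points (analytic), 2000 (numerical).

*Moments*: trapezoidal quadrature on the image grid `s_b exp(mu t_grid)`
(no interpolation).  Residual mass beyond the horizon (at most 1e-6) is
folded in by renormalizing; completions below 0.999 additionally raise a
warning.  Densities requested on custom size grids are interpolated
monotonically (PCHIP) in log-density over the strictly positive region, and
linearly near zeros.

## Calibration of the rate constant

`k` is never free.  Given the shape parameters, `k` is fixed by requiring the
predicted conditional mean `<s_d | s_b = 1>` to equal the observed mean
division size (sizes are normalized so `<s_b> = 1`).  The root is bracketed
geometrically on `ln k` and solved by Brent's method to 1e-6 relative
tolerance.  An alternative reading of the constraint — matching the
population mean of `<s_d | s_b>` over the empirical birth-size distribution —
is implemented (`mode="population"`); the conditional form is the default
because the two differ only at second order in the birth-size spread and the
conditional form needs a single solve per iteration.  In the deep commitment
regime the calibrated `k` is astronomically large (the Hill gate suppresses
it by `(s0/s)^beta`); the bracket expansion covers ~60 decades to
accommodate this.

## Likelihood and model comparison

`logL = sum_i ln rho(s_d_i | s_b_i)`.  Birth sizes are first rounded to a
0.02 grid (normalized units) — far below measurement noise — for **all**
variants alike, so the rounding cancels out of model comparisons.  Pure-birth
variants are then evaluated in closed form,
`rho(s_d|s_b) = h(s_d) Lambda^{M-1} e^{-Lambda}/(M-1)!` with `h = k_+/(mu s)`
(for the commitment gate, `Lambda` uses a tabulated cumulative hazard on a
20000-point log grid); the degradation variant runs one master-equation solve
per distinct rounded `s_b` and interpolates the log density.  Densities are
floored at 1e-300.

Fitting maximizes over the integer `M` and the continuous shape parameters,
re-calibrating `k` at every evaluation:

- `M`: ascending coarse ladder (1, 2, 3, 4, 5, 6, 8, 10, 13, 16, 20, 25, 31,
  40), early-stopped after 5 consecutive non-improving rungs, then refined
  locally (±2) around the best rung.  The profile likelihood in `M` is
  unimodal on all datasets examined, which this search exploits.
- shape parameters: coarse grid plus bounded Brent refinement (1-D:
  `gamma/mu` in [0, 20], `lambda` in [0.2, 8]) or Nelder–Mead with bounds
  (`s0` in [0.1, 5], `beta` in [0, 100]); these bounds cover the displayed
  sizer-like regimes with ample margin.  The adder-reduction endpoint
  (`gamma=0`, `lambda=1`, `beta=0`) is always evaluated, so the nested
  variants can never score below the adder beyond optimizer tolerance.

Parameter counts for the AIC (`AIC = 2 n_params - 2 logL`): adder 1 (`M`),
degradation 2 (`gamma, M`), power_law 2 (`lambda, M`), commitment 3
(`s0, beta, M`); the calibrated `k` is excluded since it is pinned by the
mean constraint.  Models are ranked by AIC (ties broken toward fewer
parameters), the relative likelihood of model *i* is
`p_i = exp[(AIC_min - AIC_i)/2]`, and models with `p < 0.05` are flagged as
discarded.

## Simulator

Exact sampling, no time discretization error:

- Pure-birth variants are sampled in the size coordinate, where the stage
  process is an inhomogeneous Poisson process with per-size hazard
  `h(s) = k_+(s)/(mu s)`: the division size solves
  `Lambda(s_b -> s_d) = E_1 + ... + E_M` with unit exponentials `E_j`
  (closed-form inversion for adder and power law, tabulated inversion for the
  commitment gate).
- Degradation uses thinning against a piecewise-constant dominating rate
  `k_+(s at window end) + gamma m` over windows of 0.1 doubling times; since
  `k_+` increases along the growth path the bound is valid, making the scheme
  exact in distribution (and asserted at every proposal).

Lineages chain daughters by exactly symmetric division (`s_b = s_d/2`; no
septum-placement noise, which the model does not include) and discard a
50-cycle burn-in — birth sizes mix within a few cycles for every variant
tested, so 50 is conservative.  Each lineage gets an independent stream
derived from (master seed, lineage index), making parallel generation
reproducible.

## Synthetic data

The generator emulates mother-machine lineage data: one long lineage per
condition, normalized by the empirical mean birth size.  Defaults: 10000
cycles per condition (5000 for the benchmark suite used in recovery tests),
`mu = ln 2`, no measurement noise — fits act on raw lengths; a multiplicative
log-normal noise option (suggested sd 0.02, reflecting instrumental
precision) exists to probe robustness.  The benchmark suite covers an adder
control plus weak/strong sizer-like regimes per mechanism
(`gamma/mu` in {0.5, 2}, `lambda` in {2, 4}, `(s0, beta)` in {(1.5, 4),
(2.5, 20)}), all with `M = 10` — giving the adder control `CV2_Delta = 0.1`,
the magnitude typical of slow-growing *E. coli* mother-machine data — and
`k` calibrated so the mean added size equals the mean birth size.

What the generator does **not** emulate: segmentation artifacts, cell-width
fluctuations, growth-rate variability between cells, mother/daughter
correlations beyond size halving, filamentation or death.  Passing recovery
tests therefore demonstrate identifiability of the mechanisms under the
model's own idealized sampling, not robustness to all real-data pathologies
(the measurement-noise option probes the first of these).

## Binned statistics

Quantile splitting sorts cycles by `s_b` (stable sort; deterministic under
ties) into equal-count bins — the remainder spread from the lowest bin up —
and reports per-bin `<s_b>`, `<Delta>` and within-bin
`var(Delta)/<Delta>^2` (population variance, matching the moment-based
definition of the noise signature).  Intervals are percentile bootstrap
(default 1000 resamples, 95%); BCa refinements are unnecessary at these
sample sizes.  The `Delta`–`s_b` association is a Pearson correlation by
default (Spearman available); "adder-compatible" means its bootstrap CI
includes zero.

## Test problem sizes

The suite checks closed forms at solver defaults (seconds), simulator/solver
agreement by KS tests at n = 1e4 per variant and parameter set, and
ground-truth recovery by running the full four-variant comparison on the
adder control and the three strong-regime benchmark datasets over three
replicate seeds (n = 5000 each), requiring the generating mechanism to win
the AIC ranking in the majority of replicates.  More seeds sharpen the
recovery statistics at proportional cost; three replicates keep the default
run comfortably interactive.

## Known limitations

- The degradation variant's likelihood is ~30x more expensive than the
  closed-form variants; a four-variant comparison on 5000 cycles takes about
  a minute on one core.
- Near-boundary fits (`beta -> 0`, commitment) leave `s0` unidentifiable;
  the reported `s0` is then arbitrary within its bounds.
- AIC separates mechanisms reliably only in clearly sizer-like regimes; for
  adder-like data all four variants fit comparably and the ranking among
  them is statistical noise (the adder then wins on parsimony in most, not
  all, replicates).
- Raw-unit quantities (e.g. mean birth length in microns) are reported only
  as the stored normalization constant; all model conclusions are scale-free.
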