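# Methods

## Model

The package fits a two-phase level-change model to a single AB series of
n outcome observations with an unknown discrete change point:

- mean: μ_t = β11 for t < CP, μ_t = β21 for t ≥ CP;
- errors: stationary AR(1), e_t = ρ e_{t−1} + ε_t with ε_t ~ N(0, σ²) and
  e_1 drawn from the stationary distribution N(0, σ²/(1−ρ²)).

The likelihood is the exact stationary Gaussian AR(1) density.  A
conditional-on-first-observation variant (`stationary=False`) is available
for sensitivity analysis; it drops the first factor, which matters on
series this short.  CP is discrete: it indexes the first intervention-phase
observation, matching weekly assessment occasions.  Its posterior mean can
still be non-integer because it averages over the discrete posterior.  The
CP support excludes indices leaving fewer than `min_per_phase` (default 3)
observations in either phase — the model is not applied below that.

## Priors

| parameter | prior | default hyperparameters |
|---|---|---|
| β11, β21 | Normal(μ₀, τ₀²) | μ₀ = mean(y), τ₀ = 10·sd(y) |
| σ | Uniform(0, u) | u = 5·sd(y) |
| ρ | Normal(0, 0.2²) truncated to (−1, 1) | `rho_sd=0.2`; `None` → Uniform(−1,1) |
| CP | discrete uniform | over the admissible support |

The intercept and σ priors are weakly informative on the outcome's own
scale.  The ρ prior is deliberately not flat: a series of ~18 points
carries almost no information about lag-1 autocorrelation, and under a
Uniform(−1, 1) prior a non-negligible share of posterior mass sits near
|ρ| = 1, where a near-random-walk error process can imitate any level
shift and the phase intercepts lose identification (we confirmed this with
the grid oracle: 10–25% posterior mass at ρ > 0.7 on responder-type
series).  Shrinking ρ toward zero encodes the design assumption that
week-to-week carry-over in a stable caregiver-rated trait instrument is
modest, while still allowing |ρ| ≈ 0.4 within two prior SDs.  Users who
want the flat prior set `rho_sd=None` in `BucpPriors`.

## Sampler

One Gibbs-style sweep per iteration:

1. CP: exact categorical draw from its full conditional (support
   enumerated, conditional likelihood × prior normalized).
2. (β11, β21): joint conjugate bivariate-normal draw after whitening the
   AR(1) model (first row scaled by √(1−ρ²), later rows lag-differenced).
3. σ: random-walk Metropolis on log σ (Jacobian included).
4. ρ: random-walk Metropolis on atanh ρ (Jacobian log(1−ρ²) included).

Step sizes adapt toward 0.44 acceptance during burn-in only and are frozen
afterwards, so the retained draws target the exact posterior.  Chains start
overdispersed (phase means ± jitter for the intercepts, sample SD × a
cycling factor for σ, ρ cycling over {0, ±0.5, 0.25}, CP spread across its
support).  A master seed expands into per-chain substreams via
`numpy.random.SeedSequence` spawn keys; runs are bitwise reproducible.

Defaults are 4 chains × 30,000 post-burn-in draws (120,000 retained in
total) with 5,000 burn-in per chain and no thinning.  The recovery /
operating-characteristic runs in the test suite use 4 × 10,000 draws with
1,000 burn-in per fit: the CP and intercept updates are exact/conjugate and
equilibrate within tens of sweeps, so a short adaptation window suffices,
and 40,000 retained draws give credible-interval endpoints stable to well
below the decision rules' resolution.

## Diagnostics and decisions

PSRF is the classic two-part Gelman–Rubin statistic
√(((n−1)/n·W + B/n)/W) with W the mean within-chain variance and
B = n·Var(chain means); two identical chains give √((n−1)/n).  A
split-chain variant is selectable.  Convergence requires PSRF < 1.05 for
every monitored parameter (cp, β11, β21, σ, ρ, es).

Credible intervals are equal-tailed 2.5/97.5 percentiles with linear
interpolation (not HPD).  For the discrete CP the percentile interval can
exclude the posterior mean; reports keep the raw quantiles.

The effect size is computed per retained draw, es = (β21 − β11)/σ, pooled
across chains, so es has a genuine posterior distribution.  Two
conventions deserve note: the standardized mean difference is often
written (β11 − β21)/σ_β yet reported positive when phase B exceeds phase
A; we adopt positive-equals-improvement and print a footnote in every
report.  And σ_β is taken to be the residual-SD draw (mean of ratios), not
a ratio of posterior means; the two differ slightly (Jensen gap), which is
why a plug-in ratio of posterior means only approximates the posterior
mean of es.

Significance requires both: non-overlapping phase 95% CIs (closed
intervals — touching counts as overlap) and an es 95% CI excluding zero
(zero on the boundary counts as included).  Widening any interval can only
remove significance, never create it.

## Synthetic data

The generator draws exactly the process the model assumes: a step mean
with stationary AR(1) noise.  Scenario defaults (n = 18 weekly points,
intervention onset at index 10, ABC-DS total-score scale):

- `responder`: β11 = 78, β21 = 82.5, σ = 1.2, ρ = 0 — a standardized level
  shift of 3.75, the magnitude seen when an intervention clearly works;
- `stable_null`: β11 = β21 = 67, σ = 3.5, ρ = 0 — no effect, noisy weeks;
- `drifting_null`: β11 = β21 = 85, σ = 3.8, ρ = 0.3 — no effect with
  autocorrelated drift.

Integer rounding/clipping to the instrument range is off by default
because the fitted model is continuous-normal; it is enabled only for
fixtures that must look like raw integer scale scores.  The generator does
not emulate item-level responses, rater effects, floor/ceiling
psychometrics, or missing weeks — so passing operating-characteristic
tests demonstrate correct inference under the model's own assumptions, not
robustness to their violation.

## Oracles

`enumerate_cp_posterior` is exact for ρ = 0: the likelihood factorizes
across phases, each phase's intercept integrates out in closed form
(Sherman–Morrison on σ²I + τ₀²J), and σ is integrated numerically with a
400-point midpoint rule over its uniform prior.  `grid_posterior` covers
ρ ≠ 0 by dense-grid quadrature (defaults: 81-point intercept grids over
data range ± 3·sd(y), 48-point σ grid, capped at 10⁷ joint evaluations).
Sampler-vs-oracle agreement (total-variation distance < 0.05 on the CP
posterior; continuous means within 3 Monte-Carlo SEs) is the primary
correctness gate in the test suite.

## Numerical notes and limitations

- Batch-means MCSE (30 batches) is used for Monte-Carlo error bars.
- The CP categorical draw subtracts the max log-weight before
  exponentiating; the conjugate 2×2 solve uses a closed-form Cholesky.
- Degenerate inputs: a flat series gets a unit prior scale fallback;
  σ → 0 fixtures are handled by the exact CP conditional (posterior mass
  collapses onto the true index).
- Missing weeks are rejected by default (`allow_gaps=True` keeps gaps
  visible in the timepoints but the likelihood currently assumes
  contiguous observations; exact AR(1) gap-skipping is not implemented).
- Only level (intercept) changes are modelled: no slope change, no
  multiple change points, no non-normal outcome families.
- With ~18 observations the data cannot distinguish strong autocorrelation
  from a level shift; conclusions about ρ are prior-driven by design (see
  Priors).
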