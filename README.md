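# bucp — Bayesian unknown change-point analysis for single-case AB designs

`bucp` fits interrupted time series from single-case experimental designs
(SCEDs): one participant, repeatedly measured, with a baseline phase (A) and
an intervention phase (B).  It was built for short weekly series of clinical
outcome scales — in particular the ABC Dementia Scale (ABC-DS), a 13-item
caregiver-rated instrument (items scored 1–9, higher = milder dementia) with
ADL, BPSD and cognitive-function subscales — but works for any AB series
with at least three observations per phase.

## The model

An AB series y_1, …, y_n is modelled as a level shift at an unknown discrete
change point CP with AR(1)-correlated normal errors:

```
y_t = β11 + e_t      for t < CP       (phase-A intercept)
y_t = β21 + e_t      for t ≥ CP       (phase-B intercept)
e_t = ρ e_{t−1} + ε_t,   ε_t ~ N(0, σ²),   e_1 ~ N(0, σ²/(1−ρ²))
```

All five parameters (β11, β21, σ, ρ, CP) are estimated jointly by
multi-chain MCMC: the CP is drawn exactly from its enumerated full
conditional, the intercepts by a conjugate bivariate-normal draw under the
whitened AR(1) model, and σ and ρ by adaptive random-walk Metropolis.
Convergence is assessed with the Gelman–Rubin potential scale reduction
factor (PSRF); a fit is accepted when every parameter's PSRF < 1.05.

The intervention effect is summarized by the standardized mean difference
computed per posterior draw, es = (β21 − β11)/σ (positive = improvement),
and two decision rules: the 95% equal-tailed credible intervals of β11 and
β21 must not overlap, and the 95% credible interval of es must exclude
zero.  Both must hold for the effect to be called significant.

A brute-force oracle module (exact enumeration for ρ = 0, dense-grid
quadrature otherwise) provides reference posteriors that the sampler is
validated against in the test suite.

## Worked example

Simulate a clear responder (level shift of 4.5 score points on σ = 1.2
noise, onset at week 10) and fit it:

```
bucp simulate --scenario responder --seed 1 --out series.csv
bucp fit --input series.csv --onset 10 --seed 2 \
         --iterations 5000 --burn-in 1000 --out-dir out
```

which prints (abridged):

```
BUCP fit report — outcome: score

parameter          Mean (SD)         95% Bayesian CI    PSRF
cp             9.49 (1.18)  [    7.00,    12.00]   1.000
beta11        77.90 (0.59)  [   76.70,    79.08]   1.000
beta21        81.90 (0.64)  [   80.58,    83.10]   1.000
sigma          1.47 (0.31)  [    0.99,     2.19]   1.000
rho            0.03 (0.17)  [   -0.30,     0.39]   1.000
es             2.84 (0.80)  [    1.27,     4.44]   1.000

converged (all PSRF < 1.05): True
phase CIs overlap: False
es CI excludes zero: True
significant: True
```

The change-point posterior centres on the true onset (week 10), the phase
intercepts recover the simulated levels 78 and 82.5 with non-overlapping
credible intervals, and the effect-size interval [1.27, 4.44] excludes
zero — the two decision rules agree that the simulated intervention
worked.  `out/` additionally receives `report.json`,
`report.csv`, and the fully-resolved run configuration for audit.

Operating characteristics of the whole pipeline (detection rate under a
true effect, false-positive rate under a null, change-point localization
error) are available via `bucp recover --scenario responder --seed 1`.

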