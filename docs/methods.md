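# Methods

`jmclaims` implements a shared-random-effects joint model for yearly
emergency-claim counts and time to death in an insured population aged
65+, together with everything needed to study it end to end without
access to a real portfolio: a generative simulator, maximum-likelihood
estimation, dynamic individualized survival prediction, and
prediction-error evaluation.

## Model

For subject *i* with entry age `age0_i`, sex `sex_i` (man 0 / woman 1)
and yearly claim counts transformed as `y_ij = log(1 + count_ij)`:

```
y_i(t)  = m_i(t) + eps_i(t)          eps ~ N(0, sigma^2)
m_i(t)  = (beta0 + b_i0) + (beta1 + b_i1) t
b_i     ~ N(0, D),  D = [[sd_b0^2, rho sd_b0 sd_b1], [., sd_b1^2]]

h_i(t)  = h0(t) exp{ gamma' w_i + alpha F(m_i(t)) }
w_i     = (sex_i, age0_i, sex_i * age0_i)
F(t)    = \int_0^t wbar(t - s) m_i(s) ds
```

The weighted cumulative effect `F` integrates the *expected* trajectory
(not the noisy observations) against a fading kernel `wbar`, so recent
claim activity weighs more than old activity in the hazard.  `alpha` is
the log-hazard change per unit of `F`.  Time is measured in years since
study entry; age enters only through the baseline covariate `age0`.
`h0` is an exponentiated cubic B-spline on `[0, tau]` with `tau` the
longest observed follow-up, which keeps the baseline positive and makes
subject-specific prediction possible (a partial-likelihood baseline
would not).  The separate survival analysis, by contrast, is a standard
Cox fit (Efron ties) with the baseline left unspecified.

### Fading kernels

Three families are provided, each integrating to 1 over `[0, inf)`:
exponential (`lam e^{-lam u}`), uniform over a window `L`, and linear
decay over a window `L`.  The default is the exponential kernel with
`lam = -log(1 - p)`, `p = 0.95`, i.e. 95% of the weight falls in the
most recent year (`lam ~ 3.0` per year).  The share `p` is a tunable:
the evidence for a dominant final-year weight is qualitative, so the
rate is exposed in configuration rather than hard-coded.  A
`normalize="interval"` variant rescales the kernel to unit mass over
the realised history `[0, t]`; the default keeps the `[0, inf)`
normalization, under which `F` obeys `dF/dt = lam (m(t) - F(t))` for
the exponential family (checked numerically in the tests).  Whether `F`
should apply to the expected trajectory or the raw observations is a
genuine modelling fork; the expected trajectory is used, consistent
with the hazard being a function of the latent health state.

### Association modes

Besides the default weighted-cumulative feature, the hazard can use the
current value `m_i(t)` or the pair `(m_i(t), m_i'(t))` with two
association coefficients (a rate-of-change sensitivity analysis).  All
three run through the same fitting code.

## Estimation

The marginal likelihood integrates each subject's longitudinal density,
survival density and random-effect prior over `b_i`.  The integral is
evaluated by **pseudo-adaptive Gauss–Hermite quadrature**: a product
Hermite grid (default 9 nodes per dimension) recentred and rescaled at
the subject's empirical-Bayes posterior from the separate longitudinal
fit.  Cumulative hazards use a nested Gauss–Legendre rule: an outer
rule (7 nodes per panel) on `[0, t]` for the hazard and a 15-node inner
rule for the kernel moments `W0(t) = int wbar(t-s) ds` and
`W1(t) = int wbar(t-s) s ds`; because `m_i` is linear in time,
`F = a W0 + b W1` exactly, so the inner rule never needs the trajectory
itself.  The inner rule is restricted to the kernel support (the
windowed kernels kink there), with composite panels spanning at most
five e-foldings of the exponential kernel.  The outer rule, wherever
oracle accuracy matters — the public cumulative-hazard routine and all
prediction-time hazards — is a composite rule split at the spline knots
(an exponentiated piecewise cubic is not a polynomial).  Both were
verified against 10^6-point trapezoid oracles (relative error below
1e-6) and the whole subject likelihood against a 401^2 tensor-grid
integration (relative error < 1e-6; see the test suite).  Inside the
fitted likelihood itself the outer rule is the plain 7-node rule on
`[0, T_i]`: that fixed quadrature is part of the estimator's definition
(deterministic given the rule sizes), and the ~1e-3 relative error it leaves
on a cumulative hazard of order 0.1 is negligible against sampling
error at the cohort sizes of interest while keeping each likelihood
evaluation cheap enough for the replicate studies.

Maximisation is direct quasi-Newton (L-BFGS-B) on an unconstrained
scale (log SDs, atanh correlation) with an **analytic gradient**
(verified against central differences at ~6e-8) and diagonal
preconditioning from the initial Hessian.  Standard errors come from
the observed information, computed by central differences of the
analytic gradient and delta-method-mapped to the natural scale.  ML
(not REML) is used everywhere so AIC and likelihood-ratio comparisons
across separate and joint fits are coherent.  AIC counts all free
parameters including the spline coefficients; candidate kernels share
the spline dimension, so rankings are unaffected by that convention.

Two internal reparametrizations are recorded on the fitted object and
applied consistently in prediction: covariates are centered at their
cohort means, and the association feature is centered at its
empirical-Bayes cohort mean.  Both offsets are absorbed into the spline
baseline level and leave `gamma` and `alpha` untouched; they exist
purely to decorrelate the baseline level from the other coefficients
(without them the optimiser needs an order of magnitude more
iterations).

### Quadrature near variance boundaries

A fixed Hermite grid cannot follow the integrand when the
random-effects distribution degenerates.  Two safeguards address this:

* The variance components are constrained away from the degenerate
  corner during optimisation (`sd_b0, sigma >= 0.01`, `sd_b1 >= 0.005`,
  `|rho| <= 0.95`) — far outside any plausible estimate on the log1p
  scale, but enough to prevent the optimiser from exploiting spurious
  quadrature spikes along the `|rho| -> 1` knife edge.
* **Pseudo-adaptive rounds**: the grid is held fixed within each
  quasi-Newton run; at the candidate optimum it is rebuilt from the
  fitted longitudinal parameters and the log-likelihood re-evaluated.
  If the value moves by more than 0.05, the optimisation restarts on
  the new grid (at most 5 rounds).  This matters exactly when a
  variance component heads to its boundary (e.g. the random-slope LRT
  under the null): without it the nested models' log-likelihoods are
  not comparable and the boundary LRT is badly oversized (0.55
  empirical size at nominal 0.05 in a 40-replicate study); with it the
  empirical size is 0.025.

The random-slope LRT refers `2 (ll1 - ll0)` to the 50:50 mixture of
chi-square(1) and chi-square(2), the correct reference when a variance
sits on the boundary under the null.  Statistics between -0.5 and 0 are
clamped to zero with a warning (boundary fits can undershoot the nested
model by a whisker); larger negative values raise, signalling a
convergence failure.

## Prediction

For a subject alive at time `t`, `pi(u|t)` is estimated by Monte Carlo
over two sources of uncertainty (200 draws by default, matching the
convention of reporting medians with 95% pointwise bands over 200
samples):

1. parameters from the asymptotic posterior `N(theta_hat, V)` on the
   unconstrained scale, mapped back (a non-PSD `V` is projected by
   eigenvalue clipping and flagged);
2. random effects from `p(b | records <= t, T* > t, theta_l)` by
   Metropolis–Hastings: 25 steps, Gaussian proposal centred with the
   posterior-mode curvature scaled by `2.4^2 / dim`, final state taken.
   All chains run vectorised; the proposal is built once per subject at
   `theta_hat` (a valid MH scheme for every target).

Each draw contributes `exp(-(Lambda(u) - Lambda(t)))`; the mean,
median and 2.5/97.5% quantiles are reported pointwise.  Mean and median
are both reported because they are both conventional summaries of the
Monte Carlo distribution.  Predictions are capped at the spline
boundary `tau`: with no events observed beyond the study window the
hazard there is unidentified.  In the exactly-degenerate configuration
(`V = 0`, `sigma = 0`, consistent records) the posterior is a point
mass and the machinery returns zero-width bands exactly.

The **prediction error** with absolute loss at horizon `u` given base
time `t` averages, over subjects at risk at `t`,

```
|1{alive at u} - pi_i(u|t)|                              status known
pi_i(u|c) |1 - pi_i(u|t)| + (1 - pi_i(u|c)) |0 - pi_i(u|t)|   censored at c in (t,u)
```

i.e. a subject censored inside the window is split between the two
outcomes by its own model-based continuation probability rather than
dropped (dropping censored-in-window subjects would bias the estimate
toward the survivors).  The exact weighting for censored-in-window
subjects is a documented choice, oracle-tested against an independent
hand-coded implementation.  The default per-subject probability is a
deterministic plug-in at `theta_hat`: the conditional-survival ratio
integrated over the exact posterior of `b` with a mode-recentred
Hermite rule — no Monte Carlo noise, which keeps the estimator
reproducible and fast.  The covariates-only benchmark uses the
spline-baseline PH fit without longitudinal input.

## Synthetic portfolio

The generator draws cohorts from exactly the model above, under a
default regime emulating an elderly insured portfolio:

| parameter | default | meaning |
|---|---|---|
| `beta` | (0.319, 0.014) | population log1p-claims intercept/slope per year |
| `sd_b0`, `sd_b1`, `corr_b` | 0.329, 0.050, -0.2 | random-effect SDs and correlation |
| `sigma` | 0.471 | residual SD on the log1p scale |
| `gamma` | (-4.648, 0.095, 0.059) | sex, entry-age, interaction log-hazard effects |
| `alpha` | 1.462 | association with the weighted cumulative effect |
| `baseline_rate` | 6.4e-6 /yr | constant latent baseline hazard |
| `admin_censor` | 8.08 yr | administrative study window |
| `dropout_rate` | 0.0858 /yr | external (non-informative) censoring rate |
| `sex_prob` | 0.605 | probability of code 1 (woman) |
| `age0` | 65 + Gamma(2, 4.1/4.6) | entry age, scale by sex (means 73.2 / 74.2) |

Measurement occasions are yearly from entry (optional uniform jitter),
truncated at follow-up; every subject keeps a baseline occasion.  The
continuous `y` path is the model-faithful response consumed by fitting;
an integer count view `max(0, round(exp(y) - 1))` is provided because
real ingestion starts from counts, but no count-level distribution is
claimed.  Latent death times invert the subject cumulative hazard at an
Exponential(1) draw by monotone bisection (relative tolerance 1e-8,
hard horizon 200 years with flagged escapes).  The dropout rate is set
so about half the portfolio remains at the administrative close, and
the baseline rate was calibrated once, by a pilot run, to the ~92%
censoring regime (pilot over 20 cohorts of n = 500: censoring fraction
0.914 +/- 0.014; the test band [0.86, 0.97] was declared from that
pilot).  The correlation -0.2 and the Gamma-shaped entry-age
distribution are choices where no empirical value was available.

What the generator does *not* emulate: the empirical count
distribution of a real portfolio beyond the Gaussian log1p model,
informative censoring, delayed-entry risk sets (entry age is a
covariate, not a time scale), or calendar-time effects.  Passing tests
therefore demonstrate internal correctness and statistical calibration
under the stated model, not fidelity to any particular insurer's data.

## Problem sizes used in the checks

The replicate studies are scaled to desk size as the package's own
reference experiment sizes: single recovery fits use 500 subjects;
interval-coverage uses 50 replicates of 250; the boundary-LRT size
study 40 replicates of 150; kernel selection 20 replicates of 250 with
candidates {exponential lam~3, uniform 4 yr, linear decay 6 yr} chosen
to span fast and slow fading; calibration uses an 800-subject cohort
split in halves.  Joint fits in replicate loops use 2 interior spline
knots (6 basis functions) — at ~20 events per replicate cohort a denser
baseline basis is not identifiable — while the module default is 5
interior knots at event-time quantiles.

## Known limitations

* The spline baseline is unidentified beyond the last event time;
  predictions are capped at `tau` rather than extrapolated.
* Pseudo-adaptive quadrature is accurate only within the bounded
  variance region described above; estimates sitting exactly on those
  bounds should be read as boundary solutions.
* The asymptotic-posterior Monte Carlo prediction propagates sampling
  uncertainty through `N(theta_hat, V)`; it is not a full Bayesian
  treatment of the posterior.
* No competing risks, recurrent events, left truncation on the age
  scale, or count-distribution (Poisson/NB) modelling.
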