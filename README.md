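# jmclaims

Joint modelling of longitudinal emergency-claim counts and survival in
elderly insured populations, with recency-weighted cumulative effects
and dynamic individualized survival prediction.

## The problem

Health insurers observe, for each policyholder aged 65+, a yearly count
of hospital admissions, emergency-room visits and ambulance calls, plus
the time of death or censoring.  Claim activity and mortality are not
independent: subjects whose demand for non-routine care is rising are
the subjects whose hazard of death is rising.  Modelling the two
processes separately biases both; a *joint model* ties them through
shared subject-level random effects and lets the claims history enter
the hazard directly.  `jmclaims` is written for biostatisticians and
actuaries who want that workflow — estimation, testing, model selection
and per-subject prediction — in a reproducible package, with a
synthetic-portfolio generator standing in for proprietary data.

## The model

With `y_ij = log(1 + count_ij)` measured at yearly occasions `t_ij`:

```
y_i(t) = m_i(t) + eps_i(t)            eps ~ N(0, sigma^2)
m_i(t) = (beta0 + b_i0) + (beta1 + b_i1) t,     b_i ~ N(0, D)

h_i(t | M_i(t), w_i) = h0(t) exp{ gamma' w_i + alpha F(m_i(t)) }
F(t) = \int_0^t wbar(t - s) m_i(s) ds
```

where `w_i = (sex, age0, sex x age0)`, `h0` is an exponentiated cubic
B-spline, and `wbar` is a fading kernel (exponential by default, with
95% of its weight in the most recent year) so recent claims matter more
than old ones.  `alpha` measures the log-hazard increase per unit of
recency-weighted cumulative claim intensity.  The package also fits the
two sub-models separately (ML mixed model; Cox partial likelihood) for
comparison, ranks alternative kernels by AIC, tests the random slope
with a boundary-corrected likelihood-ratio test, and estimates
`pi(u|t)` — the probability a subject alive at `t` survives to `u` —
by Monte Carlo over the asymptotic parameter posterior and a
Metropolis–Hastings draw of the subject's random effects, updated as
new yearly measurements arrive.  See `docs/methods.md` for the full
account.

## Worked example

```python
import numpy as np
import jmclaims as jm
from jmclaims.simulate import SimulationConfig, simulate_cohort

config = SimulationConfig(n_subjects=500)   # reference portfolio regime
cohort = simulate_cohort(config, seed=42)

fit = jm.fit_joint(cohort, n_interior=2)
p = fit.params
print(f"alpha = {p.alpha[0]:.3f} (SE {fit.se['alpha']:.3f})")

subject = max((s for s in cohort.subjects if s.delta == 0),
              key=lambda s: len(s.records))
pred = jm.predict_survival(fit, subject, 3.0, np.array([3.0, 5.0, 7.0]),
                           n_draws=200, rng=0)
print(pred.to_frame().round(3).to_string(index=False))
```

prints

```
alpha = 1.519 (SE 0.602)
  u  mean  median  lower95  upper95
3.0 1.000   1.000    1.000    1.000
5.0 0.955   0.961    0.884    0.982
7.0 0.898   0.911    0.762    0.960
```

The cohort had 41 deaths among 500 subjects (91.8% censored).  The
fitted association is strongly positive — about a 4.6-fold hazard
ratio per unit of weighted cumulative log-claims (`exp(1.519)`), within
one standard error of the generating value 1.462.  The prediction block
reads: conditional on this subject being alive at year 3 with their
claim history to date, the model puts mean survival at 0.955 by year 5
and 0.898 by year 7, with 95% Monte Carlo bands from the 200 draws.

A command-line interface mirrors the library:

```bash
jmclaims simulate --config sim.yaml --seed 1 --out panel.csv --truth-out truth.json
jmclaims summarize --data panel.csv
jmclaims fit-joint --data panel.csv --config fit.yaml --out fit.json
jmclaims evaluate --data panel.csv --t 5 --u 7 --out pe.json
```

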