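# cogscreen

Analytics for brief cognitive-impairment (CI) screening batteries in
elderly primary-care populations. The package scores multi-instrument
dichotomous item responses with a **higher-order two-parameter logistic
(2PL) IRT model**, builds **composite risk scores**, compares
**fixed-threshold classification** against a grid-searched
**machine-learning model zoo**, and quantifies stability with
**bootstrap evaluation** — all exercisable end-to-end on a synthetic
cohort, and verified against a packaged 86-patient reference score
table (67 normal cognition, 19 CI).

## The model

Five instruments measure distinct cognitive domains — Dimensional
Change Card Sort (DCCS, cognitive flexibility, 30 items), Picture
Sequence Memory (PSM, episodic memory, 12), Arrow Matching (ARW,
inhibitory control, 50), Sequences (MFS, working memory, 30) and
Number-Symbol Match (NSM, processing speed, 144). Item *j* of domain
*d(j)* is answered correctly with probability

```
P(y_ij = 1 | θ) = σ( a_j (θ_{i,d(j)} − b_j) )
```

and the domain abilities load on a single general factor,

```
θ_d = λ_d θ_g + ε_d,   ε_d ~ N(0, 1 − λ_d²),   θ_g ~ N(0, 1),
```

so every ability has unit marginal variance and 0 < λ_d < 1 fixes
scale and reflection. Estimation is Metropolis-within-Gibbs MCMC; the
posterior-mean (EAP) general ability is the overall score — `SSHO2D`
when fitted to the two-instrument battery {DCCS, PSM}, `SSHO` for all
five. Composite scores are ordinary least squares of the 0/1 CI label
on a handful of score features pushed through a logistic transform,
P = σ(β₀ + Σβₖxₖ) (deliberately OLS-then-sigmoid, matching the
reference coefficient table). Classification is either a strict
threshold on one score or one of seven grid-searched sklearn
classifiers (SVC, logistic regression, decision tree, KNN, random
forest, gradient boosting, MLP), evaluated by confusion-matrix metrics
with CI as the positive class and by 100-round
resample-with-replacement bootstrap.

## Worked example

```python
import numpy as np
from cogscreen import (CohortSimConfig, generate_cohort, HigherOrderIRT, HOIRTConfig,
                       classify_by_cut, count_mismatches, CutRule,
                       load_printed_fixture_frame)

# 1. the packaged reference table: a fixed cut on the overall score
fx = load_printed_fixture_frame()
preds = classify_by_cut(fx.ssho2d.to_numpy(), CutRule(-0.026, "impaired-if-below"))
print("mismatches:", count_mismatches(preds, fx.impaired.to_numpy()))

# 2. score a synthetic cohort with the two-instrument model
records, truth = generate_cohort(CohortSimConfig(n=86, seed=0))
res = HigherOrderIRT.from_cohort(records, ("DCCS", "PSM")).fit(
    HOIRTConfig(domains=("DCCS", "PSM"), n_iter=1200, n_burn=400, seed=0))
print(res.summary())
print("corr(EAP, true theta_g):", round(np.corrcoef(res.eap_theta_g, truth.theta_g)[0, 1], 3))
```

prints

```
mismatches: 14
Higher-order 2PL IRT (Metropolis-within-Gibbs)
  patients: 86  items: 42  domains: DCCS, PSM
  chain: 1200 iterations, 400 burn-in, thin 1, seed 0
  retained draws: 800
  acceptance rates: theta_d=0.44, items=0.40, lambda=0.46

  loading (EAP) per domain:
      DCCS: lambda = 0.716
       PSM: lambda = 0.760
  items: a in [0.47, 2.61] (mean 1.10); b in [-1.49, 2.19] (mean 0.30)
corr(EAP, true theta_g): 0.816
```

The 14 mismatches are the fixed-cut error on all 86 reference
patients: a single threshold on the overall score misclassifies 16% of
the cohort, which is the motivation for the machine-learned
alternatives. The MCMC summary shows healthy acceptance rates and
loadings near 0.7–0.8 — each domain shares roughly half its variance
with the general factor — and the EAP score correlates 0.82 with the
generating ability, close to the information ceiling of a
two-domain, 42-item battery.

A `cogscreen` CLI wraps the same functionality
(`cogscreen simulate | fit-hoirt | score | cuts | bench | bootstrap |
run | verify`); `cogscreen run config.yaml` executes the whole
pipeline from a YAML config and emits reproducible, hash-stamped CSV
report tables.

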