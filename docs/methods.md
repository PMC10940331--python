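# Methods

## Measurement model

Responses are dichotomous (correct/incorrect) across five instruments
with 30, 12, 50, 30 and 144 items. The two-parameter logistic item
response function is used without the historical 1.7 scaling constant:
P(correct) = σ(a_j(θ − b_j)) with discrimination a_j > 0 and difficulty
b_j on the ability scale. The higher-order structure places the D
domain abilities on a single general factor, θ_d = λ_d θ_g + ε_d with
ε_d ~ N(0, 1 − λ_d²) and θ_g ~ N(0, 1). This identification gives every
ability unit marginal variance; constraining λ_d to (0, 1) resolves the
reflection invariance. Scores from any equivalent parameterization
differ from ours by a monotone transformation, which the downstream cut
search and classifiers are invariant to; only the packaged reference
score table — not refitted scores — is used where printed values are
compared exactly.

Missing responses (permitted for the two adaptively terminated /
time-limited instruments, MFS and NSM) are treated as missing at
random and skipped in the likelihood; unattempted speeded items are
coded missing, not incorrect. All items are dichotomous; polytomous
models, DIF analysis and marginal-maximum-likelihood estimation are
out of scope.

## Posterior computation

Sampling is Metropolis-within-Gibbs over {a, b, λ, θ_g, θ_d}:

* **θ_g** has a conjugate normal full conditional given (θ_d, λ)
  (precision 1 + Σ_d λ_d²/(1−λ_d²)) and is Gibbs-sampled exactly.
* **θ_d** uses an element-wise Gaussian random-walk Metropolis step
  against the item likelihood of its domain plus the N(λ_d θ_g, 1−λ_d²)
  prior.
* **(log a_j, b_j)** are proposed jointly per item by Gaussian random
  walk; priors log a ~ N(0, 0.5²) and b ~ N(0, 2²) are weakly
  informative and keep a positive.
* **λ_d** is updated by a *collapsed* Metropolis step that integrates
  θ_g out analytically: marginally θ_d,i ~ N(0, Σ) with
  Σ = λλᵀ + diag(1 − λ²), so the loading does not have to chase the
  current θ_g draw. This materially improves mixing — with only two
  domains the likelihood identifies essentially the product λ₁λ₂, a
  flat ridge the conditional sampler traverses slowly.

Step sizes adapt toward a 20–50% acceptance rate in windows of 50
iterations during burn-in and are frozen afterward, preserving the
correct stationary distribution for the retained draws. Starting
values are data-driven (difficulties from logit item facilities, domain
abilities from standardized number-correct). Defaults are 5000
iterations, 2000 burn-in, thinning 1; chains are bit-reproducible under
a fixed seed. Diagnostics exposed on the results object are acceptance
rates and a crude split-chain mean z-score (which overstates
non-stationarity for autocorrelated chains and should be read as a
smoke alarm, not a test).

EAP scores are arithmetic means of retained ability draws. A known
information ceiling is worth recording: with two domains of ~20 items
and loadings near 0.7–0.8, even the exact posterior mean computed by
quadrature with the *true* item parameters correlates only ≈ 0.81 with
the generating θ_g (general-ability precision is bounded by
1 + Σλ²/(1−λ²), further reduced by item noise), so no estimator can do
better on such data.

## Composite scores

Composites are ordinary least squares of the 0/1 label on a feature
subset followed by a logistic transform of the linear predictor —
not logistic regression. The packaged coefficient table defines five
reference composites (classical scores; 5-D IRT scores + response
times; 2-D IRT scores ± age; PSM count + DCCS rate + age). The
"accuracy rate" of DCCS and ARW is number-correct divided by total
response time in 1/seconds. The second composite's response-time
coefficients (~1e-5) imply a sub-second time unit; it is flagged
(`rt_unit_warning`) and is refitted, rather than applied verbatim, on
second-scale synthetic data.

## Cut rules and search

Thresholds use strict inequalities with an explicit direction; a score
equal to the threshold is never "past" it, which exactly reproduces
the reference predicted-label columns including boundary patients.
The optimal-cut search enumerates midpoints of consecutive sorted
unique scores plus below-minimum and above-maximum sentinels in both
directions, guaranteeing the minimum never exceeds
min(#positives, #negatives); ties prefer impaired-if-below, then the
smallest threshold, making the result deterministic.

## Benchmark and bootstrap

Sixteen feature spaces combine IRT scores, classical scores, response
times, composites and integer-coded demographics. The zoo fixes one
hyperparameter grid per family: SVC (rbf, C ∈ {1,10,50,100}), L2
logistic regression (20 log-spaced strengths in [0.01, 5]; log spacing
chosen, linear was also defensible), decision tree (7 depths in
[3, 30]), KNN (neighbors ∈ {3,5,7,9}, a minimal symmetric default),
random forest (10 tree counts in [10, 500]), gradient boosting
({10,30,50}), and an MLP (2 layer layouts × 2 activations × 3 alphas ×
2 optimizers × 2 learning-rate schedules, max 1000 epochs). Model
selection is stratified 5-fold CV by mean accuracy with ties broken in
grid order. The 80/20 split puts ceil(0.2n) cases in the test side —
68/18 at n = 86. The random-forest tree-count search uses an exact
shortcut (one maximal forest per fold; a forest's first k trees equal a
separately fitted k-tree forest with the same seed), verified
tree-for-tree against the generic grid search in the tests.

Metrics come from the confusion matrix with impairment as the positive
class: precision TP/(TP+FP), recall TP/(TP+FN), specificity
TN/(TN+FP), accuracy, F = 2PR/(P+R), quadratic-weighted kappa (equal
to Cohen's kappa for binary labels) and AUC (pairwise concordance,
ties ½; probability scores where the classifier provides them). A
weighted-average convention (under which precision = recall = accuracy
for binary data) is available for comparison with reports using it.
Undefined ratios are reported as NaN and *skipped* in aggregation with
a reported skip count — never silently coerced to 0.

The bootstrap resamples all n rows with replacement, splits the
resample 80/20 stratified, grid-searches on the 80% and evaluates on
the 20%; out-of-bag rows are unused. Because duplicates of a test row
can occur in training, bootstrap means are optimistic relative to a
fully held-out protocol — this is a property of the protocol being
replicated, not a defect. Resamples are redrawn until both classes are
present (a negligible correction at 22% prevalence).

## Synthetic cohort

The generator draws the CI label first (Bernoulli, prevalence 0.22),
then shifts general ability by the configured gap (default 1 SD) with
an offset keeping the marginal mean at zero; responses follow the
higher-order 2PL model over a random item bank (a ~ LogNormal(0, 0.5),
b ~ N(0, 1), λ ∈ [0.5, 0.9]). Ages are sampled from the reference
cohort's empirical age distribution (67–93) through a Gaussian copula
whose correlation knob (default 0.27) links the age quantile to the
impairment propensity; discretization attenuates the realized
point-biserial correlation to ≈ 0.19 at the default. Response times
are lognormal with parameters moment-matched to the reference means
and SDs (ARW 47.421/11.619 s, DCCS 36.049/14.909 s, PSM 73/34 s).
MFS/NSM missingness rises linearly along item position to 0.5 and 0.9
respectively, reproducing monotone fatigue/stopping patterns.
Demographic categories (including the opaque income code "D" and
education code 777, which are preserved and never imputed) are drawn
from the reference frequency table.

What the generator deliberately does not emulate: item-level
response-time processes, education/income–ability dependence, any
age–ability link beyond the label, and within-instrument local
dependence. Consequently, passing tests demonstrate correctness of the
pipeline mechanics and estimator behaviour under the assumed model,
not performance on real clinical data. In particular, sample extremes
(e.g., the min/max of a composite's probabilities over 86 patients)
are unstable statistics: a faithful generator reproduces the bulk of a
printed score distribution but routinely exceeds the printed extremes
of one particular sample.

## Problem sizes and numerical choices

Simulation-based checks use deliberately chosen sizes: parameter
recovery at n = 500 with 2 × 20 items (4000 iterations, 1000 burn-in),
generator calibration checks at n = 1000–5000, and the pipeline smoke
run at the reference size n = 86 with short chains. Cronbach's alpha
is computed over item columns with complete data (the natural choice
under monotone missingness; listwise deletion would leave almost no
complete NSM rows) with sample variances. KMeans uses 20 restarts per
k so the inertia curve is non-increasing in practice. All randomness
flows from explicit integer seeds; every emitted table carries the
resolved-config hash and seed.
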