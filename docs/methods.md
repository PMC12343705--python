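# Methods

## Model

`mixtree` implements a finite-mixture multidimensional IRTree for four-point
rating-scale items. A response is decomposed into binary pseudo-items
(tree nodes): a *direction* node `y1` (disagree vs. agree), and, conditional
on the direction, one *extremity* node (`y2` on the disagreement branch,
`y3` on the agreement branch):

| category | y1 | y2 | y3 |
|---|---|---|---|
| 1 | 0 | 0 | – |
| 2 | 0 | 1 | – |
| 3 | 1 | – | 0 |
| 4 | 1 | – | 1 |

("–" is missing by design.) Each node is a logistic 2-PL item. The direction
node loads on the substantive trait θ only and is class-invariant,

  P(y1 = 1) = σ(α_j θ + β_1j),

which anchors the trait metric across latent classes. The extremity nodes
load on θ (scaled by a class- and item-specific proportionality constant
ω_jc) and on an extreme-response-style (ERS) factor η with an item-invariant
but class-specific loading α^ers_c:

  P(y2 = 1 | X = c) = σ(α_j ω_jc θ − α^ers_c η + β_2jc)
  P(y3 = 1 | X = c) = σ(α_j ω_jc θ + α^ers_c η + β_3jc)

The negative ERS sign at `y2` makes high η push toward the extreme
disagreement category. Classes therefore represent response *strategies*
along a satisficing–optimizing continuum: a class with large α^ers and
small ω makes extremity choices heuristically, a class with small α^ers and
large ω makes them substantively. The single-class model is the traditional
IRTree.

Person likelihoods multiply Bernoulli node terms over the observed nodes of
all items; structurally missing nodes contribute nothing (they are carried
as explicit masks, never sentinel categories). The marginal likelihood
mixes over classes with proportions π_c and integrates (θ, η) over a
bivariate standard normal with estimated correlation ρ.

Identification: latent means 0 and variances 1 in every class; α_j > 0 and
α^ers_c > 0 (log-parameterized), which also pins the reflection of both
latent axes; ω_jc unconstrained in sign (a config flag can impose ω ≥ 0);
π via softmax of C−1 free logits; ρ via atanh, clipped away from ±1.
Free-parameter bookkeeping: n_k0 = 2J + 1 + (C−1) class-invariant plus
n_kc = C(3J+1) class-specific parameters.

## Estimation

**Step 1 (measurement model).** The marginal log-likelihood is maximized
directly with L-BFGS-B and fully analytic gradients. A classic EM is not
used because α_j is shared across all three nodes and all classes, so no
closed-form M-step exists; the joint posterior weights W[p, c, q] over
(class, quadrature node) still appear in every score expression and are
reused for Step 2. Integration uses a Gauss–Hermite product grid (default
15 points per dimension) rotated by the Cholesky factor of the latent
correlation matrix. Multiple starts perturb a warm anchor — for C > 1 the
anchor expands a converged single-class fit with spread class offsets —
and the best converged solution by log-likelihood is kept (defaults: 4
starts for C = 1, 8 for C > 1). Convergence: relative log-likelihood
change below 1e-6 (mapped to the optimizer's ftol on the per-person
objective), at most 2000 iterations; the accepted-iterate trajectory is
monitored and any objective increase beyond 1e-8 is flagged. Class labels
are reported in descending-α^ers order (most heuristic-driven first); the
permutation is recorded.

EAP scores are posterior means over the same grid, marginal over classes;
their standard errors are posterior SDs. Note that an individual posterior
SD can exceed the prior SD of 1 when the class posterior is split between
classes with conflicting ERS interpretations (the mixture posterior is then
bimodal); only the average posterior variance is bounded by the prior
variance.

**Step 2 (classification).** Bayes posteriors over classes, modal
assignments (ties broken toward the lowest class index and logged), and the
classification-error matrix D[c, k] = (1/N) Σ_p post_pc 1[w_p = k] / P(X=c).
P(X=c) defaults to the mean posterior, which equals the fitted π̂_c at the
Step-1 optimum and makes the rows of D sum to 1 exactly.

**Step 3 (covariates).** Class membership is regressed on external
covariates by multinomial logistic regression while treating the modal
assignment as a single error-prone indicator with the fixed conditional
probabilities D — the standard correction for regressing estimated class
memberships on covariates. With D = I this reduces exactly to an ordinary
multinomial logit (verified against statsmodels in the tests). Standard
errors come from the observed information, computed by central finite
differences of the analytic gradient; they do not propagate Step-1
sampling error (a known limitation of the stepwise approach).

## Model selection and cross-validation

AIC, BIC, and a hierarchical BIC (class-specific parameters penalized by
log(π_c N)) are computed from the Step-1 likelihood with the parameter
counts above; HBIC ≤ BIC for any proper mixture, with equality at C = 1.
Separation is summarized by the relative entropy reduction
R²_entropy = 1 − Σ_p Σ_c (−post ln post) / (N ln C); this standard
definition is adopted because the statistic is conventionally reported
without a formula, and the choice is noted in every report.

The K-fold diagnostic refits the model independently on each training and
test partition, aligns the test fit's class labels to the training fit's
(exhaustive permutation search minimizing the squared distance between the
class-specific parameter blocks), and reports per fold: correlation and
*signed* mean difference of the stacked item parameters, correlation and
mean *absolute* difference of the test respondents' EAP scores and class
posteriors under the two parameter sets, and modal-assignment overlap with
Cohen's κ. The signed/absolute asymmetry is deliberate: item-parameter
differences are diagnostic of systematic shifts, score differences of
magnitude. Fold membership is a simple random split with a stored seed.

## Synthetic-data generator

The generator emulates a population of up to three response strategies:
satisficing-dominated (class 1), balanced (class 2), optimizing-dominated
(class 3). Per replication:

1. T = 3 covariates ~ N(0, I).
2. Class memberships via multinomial logit with fixed slopes — strong
   (∓1.0), weak (±0.5), null (0) — and intercepts controlling class sizes.
   The equal three-class profile uses the reference intercepts
   (0, −0.37, −0.37); all other profiles (C=2: 0.5/0.5, 0.6/0.4, 0.4/0.6;
   C=3: permutations of 0.6/0.2/0.2) are calibrated numerically by 2-D
   Gauss–Hermite quadrature so the *marginal* class probabilities hit the
   nominal sizes. Realized proportions still fluctuate with the sampled
   covariates (within about ±0.05–0.10 at these sample sizes).
3. (θ, η) ~ bivariate normal, unit variances, correlation 0 or 0.30.
4. Item parameters: α_j ~ U(0.5, 1.25), β_1j ~ N(0, 1); balanced class
   ω_j2, α^ers_2 ~ U(0.5, 0.7) and β_2j2, β_3j2 ~ N(0, 1); classes 1 and 3
   offset from class 2 by separation-controlled increments — ω down/up and
   α^ers up/down by U(0, .1), U(.2, .3) or U(.4, .5) (low/medium/high), and
   intercepts by N(0, sd) with sd = 0.25 / 0.75 / 1.5, interpreted as
   standard deviations. Increments are drawn independently per item.
   Extremity intercepts are clipped to [−3, 3]. Single-class populations
   use one strategy column with the medium-separation distributions.
5. Responses drawn from the model-implied category probabilities under
   each respondent's true class.

The full factorial (7 mixture class-size profiles × 3 N × 3 J × 2
correlations × 3 separations, plus 3 single-strategy × 3 × 3 × 2 cells,
200 replications each) enumerates 75,600 mixture and 10,800 single-class
datasets; the grid runner executes any subset with per-replication child
seeds derived from one master seed, so results are reproducible regardless
of worker count.

What the generator does *not* emulate: missing data, acquiescence or
mid-scale response styles, item-specific ERS loadings, covariate
measurement error, or non-normal latent traits. Passing recovery tests
therefore demonstrate internal consistency of model and estimator under
the stated population, not robustness to violations of it.

## Recovery metrics

Mean bias and RMSE per parameter family (after exhaustive label alignment
to the generating truth), classification hit rate (proportion assigned to
the true class), within-true-class score bias for θ and η, and mean
estimated SEs. RMSE ≥ |bias| by construction.

## Problem sizes used by the test suite

The headline recovery study is run at five replications of the two-class,
equal-size, high-separation condition with N = 2000, J = 20, 11 quadrature
points per dimension and two optimization starts per model; the
single-class selection study uses three replications at N = 1000, J = 10.
These are the package's smoke-scale defaults for routine verification; the
`simulate` command reproduces any larger slice of the factorial.

At this scale the study reproduces: classification hit rates near 0.88,
item-parameter mean biases below 0.02 in absolute value, and the
misspecification signature of a single-class fit (within-class mean ERS
bias negative for the class with the larger ERS loading, positive for the
smaller; about ±0.07–0.09 on average over replications).

## A note on AIC and class enumeration

With this likelihood fully optimized, AIC systematically prefers one class
*more* than the truth in both directions of the design: on two-class
high-separation data the three-class solution adds a tiny (π ≈ 0.04)
extra component whose log-likelihood gain (~70–85) exceeds the AIC penalty
of 62, and the same happens on single-class data. This was verified to be
a property of the global optimum, not of the optimizer: dense quadrature
(up to 31 points per dimension), pure random starts, and optimization
started from the generating truth all reproduce it, and the two-class fit
itself sits exactly where theory predicts (fitted minus truth
log-likelihood ≈ half the parameter count). AIC over-extraction of mixture
components is a well-documented phenomenon; BIC and HBIC select the true
class count decisively in the same runs and are the recommended criteria
for this model, with R²_entropy and the K-fold diagnostic as guards
against over-extraction.

## Numerical choices

- Log-sum-exp throughout the mixture/quadrature marginalization; the
  marginal log-likelihood is finite whenever any node likelihood is
  positive.
- `log_expit` for node log-probabilities (no catastrophic cancellation in
  the tails).
- Heuristic starting values from per-node observed proportions (logit of
  clipped node means), unit trait loadings, ω = α^ers = 0.6.
- Degenerate inputs: empty classes are rejected by name in the
  classification-error and HBIC computations; singular covariate matrices
  are rejected in Step 3; (quasi-)separation in Step 3 triggers a warning
  when any coefficient exceeds 10 in magnitude.
- Modal-assignment ties break toward the lowest class index and are
  logged.

## Limitations

- Four-point scales only; no mid-scale or acquiescence nodes.
- One-step (simultaneous) covariate estimation and Bayesian estimation are
  out of scope; Step-3 SEs understate total uncertainty.
- The latent correlation is class-invariant; class-specific latent
  covariance structures are not supported.
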