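# mixtree

Mixture multidimensional IRTree models for four-point rating-scale items.

## The problem

Respondents answering Likert-type items do not all arrive at their answers
the same way. Some map their standing on the measured trait carefully onto
the response categories (*optimizing*); others save effort by leaning on
content-independent habits such as the extreme response style (ERS), the
tendency to pick the endpoint categories regardless of content
(*satisficing*). IRTree models separate these influences by decomposing
each 1–4 response into binary decision nodes — a *direction* node
(disagree/agree, driven by the trait θ) and an *extremity* node (mild vs
extreme category, driven by both θ and the ERS factor η) — but classical
IRTrees assume every respondent weights θ and η identically.

`mixtree` fits a finite mixture of IRTrees in which latent classes weight
the trait and ERS differently at the extremity nodes:

- direction node (class-invariant): `P(y1=1) = σ(α_j θ + β_1j)`
- extremity nodes (class-specific): `P(y2=1 | c) = σ(α_j ω_jc θ − α^ers_c η + β_2jc)`,
  `P(y3=1 | c) = σ(α_j ω_jc θ + α^ers_c η + β_3jc)`

A class with small ω and large α^ers behaves heuristically
(satisficing-like); the reverse pattern is trait-driven
(optimizing-like). Class membership can in turn be regressed on external
covariates. The package is aimed at psychometricians and survey
methodologists who want to detect, classify and explain such response-
strategy heterogeneity.

It provides:

- marginal maximum-likelihood estimation (Gauss–Hermite quadrature,
  analytic gradients, multiple warm starts) with EAP trait/ERS scoring;
- the three-step covariate workflow: posterior classification,
  classification-error matrix, and error-corrected multinomial-logistic
  regression of class membership on covariates;
- model selection (AIC, BIC, hierarchical BIC, R²_entropy) and a K-fold
  train/test cross-validation diagnostic against over-extraction;
- a fully seeded synthetic-data generator covering a factorial design of
  class structures, sample sizes, test lengths, separations, and covariate
  effect sizes, plus bias/RMSE/hit-rate recovery metrics.

See `docs/methods.md` for the model, identification, estimation and
generator details.

## Worked example

Generate a two-class population (half satisficing-dominated, half
balanced, well separated) and recover it:

```python
import numpy as np
from mixtree import (SimulationDesign, generate_dataset, FitConfig,
                     fit_step1, posterior_class_probs, classification_error,
                     fit_step3, information_criteria, r2_entropy)

design = SimulationDesign(C_true=2, class_size_profile="equal",
                          N=2000, J=20, separation="high")
data = generate_dataset(design, seed=42)

fit = fit_step1(data.responses, C=2,
                config=FitConfig(quad_points=11, n_starts=2, seed=0))
aic, bic, hbic = information_criteria(fit.loglik, 2, 20, 2000, fit.params.pi)
post = posterior_class_probs(fit, data.responses)
err = classification_error(post.class_post, post.assignment)
covmodel = fit_step3(post.assignment, err, data.covariates)
```

Output (abridged):

```
logL = -45200.8
AIC = 90729.7, BIC = 91648.2
class proportions: [0.521 0.479]
ERS loadings:      [1.082 0.609]
mean omega:        [0.199 0.62 ]
R2_entropy = 0.686
total classification error = 0.087
covariate effects (class 2 vs 1): [-0.846  0.455 -0.008] SE [0.075 0.064 0.06]
```

Classes are reported satisficing-like first (descending ERS loading).
Class 1 weights ERS heavily (α^ers ≈ 1.08) and carries little trait into
the extremity decisions (mean ω ≈ 0.20); class 2 is balanced. The
generating values were α^ers = (1.11, 0.63) and mean ω = (0.17, 0.62), so
the strategy structure is recovered, respondents are classified with ~9%
total error, and the error-corrected Step-3 regression recovers the
strong/weak/null covariate pattern (generating slopes −1.0, +0.5, 0).

The same workflow is available from the shell:

```bash
mixtree fit --responses responses.csv --classes 2 --out run/ --seed 1
mixtree select --responses responses.csv --max-classes 4 --out run/
mixtree cv --responses responses.csv --classes 2 --folds 5 --out run/
mixtree covariates --fit run/ --responses responses.csv \
    --covariates covariates.csv --out run/
mixtree simulate --config design.yaml --out sim/ --seed 1
```

Response files are CSV with a header of item labels and integer categories
1–4 (blank = missing).

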