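"""Model selection and cross-validation diagnostics for MixTree fits.

Class enumeration is guided by information criteria (AIC, BIC, and a
hierarchical BIC that penalizes class-specific parameters by the effective
class sample size), by the entropy-based separation statistic
``R2_entropy``, and by a K-fold cross-validation suite that refits the
model independently on training and test partitions and compares item
parameters, factor scores, class posteriors, and modal assignments.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score

from .estimation import (
    FitConfig,
    FitResult,
    align_labels,
    classification_error,
    fit_step1,
    modal_assign,
    posterior_class_probs,
)
from .model import (
    MixTreeParameters,
    QuadratureGrid,
    ResponseMatrix,
    count_parameters,
    decompose_to_pseudo_items,
    posterior_weights,
)

__all__ = [
    "information_criteria",
    "r2_entropy",
    "SelectionReport",
    "select_classes",
    "KFoldReport",
    "kfold_cv",
]


def information_criteria(
    loglik: float, C: int, J: int, N: int, pi: np.ndarray
) -> tuple[float, float, float]:
    """AIC, BIC and hierarchical BIC of a fitted C-class model.

    ``AIC = -2 logL + 2 n_k``; ``BIC = -2 logL + n_k log N``;
    ``HBIC = -2 logL + n_k0 log N + sum_c n_kc/C * log(pi_c N)``, i.e. the
    class-specific parameters of class c are penalized by that class's
    expected sample size.  Natural logarithms throughout.
    """
    if N <= 0:
        raise ValueError("N must be positive")
    pi = np.asarray(pi, dtype=float)
    if pi.shape[0] != C:
        raise ValueError("pi must have one entry per class")
    n_k, n_k0, n_kc = count_parameters(C, J)
    aic = -2.0 * loglik + 2.0 * n_k
    bic = -2.0 * loglik + math.log(N) * n_k
    empty = np.nonzero(pi <= 0)[0]
    if empty.size:
        raise ValueError(f"HBIC undefined: class {empty[0] + 1} has pi = 0")
    per_class = n_kc // C  # 3J + 1 class-specific parameters per class
    hbic = -2.0 * loglik + n_k0 * math.log(N) + float(
        per_class * np.log(pi * N).sum()
    )
    return aic, bic, hbic


def r2_entropy(posterior: np.ndarray) -> float:
    """Relative entropy reduction of the posterior class memberships.

    ``1 - sum_p sum_c -post[p,c] ln post[p,c] / (N ln C)``: 0 for fully
    uncertain (uniform) posteriors, 1 for perfectly separated ones.  This is
    the standard normalized-entropy definition of mixture-model separation.
    """
    posterior = np.asarray(posterior, dtype=float)
    N, C = posterior.shape
    if C < 2:
        raise ValueError("R2_entropy is undefined for a single class")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(posterior > 0, -posterior * np.log(posterior), 0.0)
    return float(1.0 - terms.sum() / (N * math.log(C)))


@dataclasses.dataclass
class SelectionReport:
    """Per-C information criteria, separation, and class sizes."""

    table: pd.DataFrame
    fits: dict[int, FitResult]

    def best(self, criterion: str = "aic") -> int:
        """Number of classes minimizing the given criterion."""
        idx = self.table[criterion].idxmin()
        return int(self.table.loc[idx, "C"])


def select_classes(
    responses: ResponseMatrix | np.ndarray,
    max_classes: int = 4,
    config: FitConfig | None = None,
) -> SelectionReport:
    """Fit MixTree-1 .. MixTree-``max_classes`` and tabulate selection criteria."""
    if not isinstance(responses, ResponseMatrix):
        responses = ResponseMatrix(np.asarray(responses, dtype=float))
    rows = []
    fits: dict[int, FitResult] = {}
    for C in range(1, max_classes + 1):
        fit = fit_step1(responses, C, config)
        fits[C] = fit
        aic, bic, hbic = information_criteria(
            fit.loglik, C, responses.n_items, responses.n_persons, fit.params.pi
        )
        n_k, n_k0, n_kc = count_parameters(C, responses.n_items)
        post = posterior_class_probs(fit, responses)
        err = classification_error(post.class_post, post.assignment)
        rows.append(
            {
                "C": C,
                "loglik": fit.loglik,
                "aic": aic,
                "bic": bic,
                "hbic": hbic,
                "n_k": n_k,
                "n_k0": n_k0,
                "n_kc": n_kc,
                "r2_entropy": r2_entropy(post.class_post) if C > 1 else np.nan,
                "mean_diag_accuracy": err.mean_diag_accuracy,
                **{
                    f"pi_{c + 1}": fit.params.pi[c] if c < C else np.nan
                    for c in range(max_classes)
                },
            }
        )
    return SelectionReport(table=pd.DataFrame(rows), fits=fits)


# ---------------------------------------------------------------------------
# K-fold cross-validation
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class KFoldReport:
    """Per-fold and summary train-vs-test comparison metrics.

    ``item_cor``/``item_dist``: correlation and signed mean difference of
    the stacked item-parameter vectors of the two fits (item distances keep
    their sign; factor-score distances below are absolute).  ``trait_*`` and
    ``ers_*``: agreement of EAP scores for the test respondents computed
    under the training-fit vs the test-fit parameters.  ``classprob_cor``,
    ``hit`` and ``kappa``: agreement of class posteriors and modal
    assignments, after aligning the two fits' class labels.
    """

    table: pd.DataFrame
    failed_folds: list[int]


def _scores_under(
    params: MixTreeParameters,
    responses: ResponseMatrix,
    quad_points: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """EAP theta, eta, and class posterior under arbitrary parameters."""
    grid = QuadratureGrid(quad_points, params.latent_corr)
    pseudo = decompose_to_pseudo_items(responses)
    W, _ = posterior_weights(params, pseudo, grid)
    Wq = W.sum(axis=1)
    post = W.sum(axis=2)
    post /= post.sum(axis=1, keepdims=True)
    return Wq @ grid.theta, Wq @ grid.eta, post


def _item_param_vector(params: MixTreeParameters) -> np.ndarray:
    return np.concatenate(
        [
            params.alpha_trait,
            params.beta1,
            params.omega.ravel(),
            params.alpha_ers,
            params.beta2.ravel(),
            params.beta3.ravel(),
        ]
    )


def kfold_cv(
    responses: ResponseMatrix | np.ndarray,
    C: int,
    folds: int = 5,
    config: FitConfig | None = None,
    seed: int | None = None,
) -> KFoldReport:
    """K-fold stability diagnostic for a C-class MixTree.

    Respondents are split at random into ``folds`` partitions.  For each
    fold, the model is fitted independently on the training remainder and on
    the held-out test partition; the test fit's class labels are aligned to
    the training fit's, and the two solutions are compared on item
    parameters, on the test respondents' factor scores and class posteriors,
    and on modal assignments (overlap and Cohen's kappa).  Failing folds are
    recorded and skipped.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if not isinstance(responses, ResponseMatrix):
        responses = ResponseMatrix(np.asarray(responses, dtype=float))
    if config is None:
        config = FitConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    N = responses.n_persons
    order = rng.permutation(N)
    chunks = np.array_split(order, folds)

    rows = []
    failed: list[int] = []
    for k, test_idx in enumerate(chunks):
        train_idx = np.setdiff1d(order, test_idx, assume_unique=True)
        try:
            fit_train = fit_step1(
                ResponseMatrix(responses.values[train_idx]), C, config
            )
            fit_test = fit_step1(
                ResponseMatrix(responses.values[test_idx]), C, config
            )
        except RuntimeError:
            failed.append(k + 1)
            continue
        test_params, _ = align_labels(fit_train.params, fit_test.params)
        v_train = _item_param_vector(fit_train.params)
        v_test = _item_param_vector(test_params)

        test_resp = ResponseMatrix(responses.values[test_idx])
        th_tr, et_tr, post_tr = _scores_under(
            fit_train.params, test_resp, config.quad_points
        )
        th_te, et_te, post_te = _scores_under(
            test_params, test_resp, config.quad_points
        )
        w_tr = modal_assign(post_tr)
        w_te = modal_assign(post_te)
        if C > 1:
            classprob_cor = float(
                np.corrcoef(post_tr.ravel(), post_te.ravel())[0, 1]
            )
            kappa = (
                1.0
                if np.array_equal(w_tr, w_te)
                else float(cohen_kappa_score(w_tr, w_te))
            )
        else:
            classprob_cor, kappa = np.nan, np.nan
        rows.append(
            {
                "fold": k + 1,
                "item_cor": float(np.corrcoef(v_train, v_test)[0, 1]),
                "item_dist": float(np.mean(v_train - v_test)),
                "trait_cor": float(np.corrcoef(th_tr, th_te)[0, 1]),
                "trait_dist": float(np.mean(np.abs(th_tr - th_te))),
                "ers_cor": float(np.corrcoef(et_tr, et_te)[0, 1]),
                "ers_dist": float(np.mean(np.abs(et_tr - et_te))),
                "classprob_cor": classprob_cor,
                "hit": float(np.mean(w_tr == w_te)),
                "kappa": kappa,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        metrics = table.drop(columns="fold")
        summary = pd.DataFrame(
            [
                {"fold": "Mean", **metrics.mean().to_dict()},
                {"fold": "SD", **metrics.std(ddof=1).to_dict()},
            ]
        )
        table = pd.concat([table, summary], ignore_index=True)
    return KFoldReport(table=table, failed_folds=failed)
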