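"""Three-step estimation of the MixTree model.

Step 1 estimates class proportions and all item parameters by marginal
maximum likelihood, integrating the bivariate trait/ERS density on a
Gauss-Hermite grid; EAP factor scores follow from the same posterior.
Step 2 turns the fitted mixture into posterior class-membership
probabilities, modal assignments, and the C x C classification-error matrix.
Step 3 regresses the (error-prone) modal assignments on external covariates
with the classification errors held fixed as known misclassification
probabilities, which corrects the bias a naive regression of assignments on
covariates would incur.

The Step-1 objective is maximized directly with L-BFGS-B and fully analytic
gradients rather than a classic EM: the trait loading of each item is shared
across all three nodes and all classes, so no closed-form M-step exists.
Positivity of the trait and ERS loadings is enforced by log transforms,
which also pins down the reflection of both latent axes; class proportions
are parameterized as a softmax of C-1 free logits and the latent correlation
through atanh.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import warnings

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, log_expit, logsumexp, softmax

from .model import (
    LatentScores,
    MixTreeParameters,
    PseudoItemMatrix,
    QuadratureGrid,
    ResponseMatrix,
    decompose_to_pseudo_items,
    posterior_weights,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "FitResult",
    "LatentPosterior",
    "ClassificationError",
    "CovariateModel",
    "ThreeStepResult",
    "fit_step1",
    "eap_scores",
    "posterior_class_probs",
    "modal_assign",
    "classification_error",
    "fit_step3",
    "predict_class_probs",
    "align_labels",
]


# ---------------------------------------------------------------------------
# Configuration and result containers
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class FitConfig:
    """Settings for the Step-1 marginal ML fit.

    ``n_starts`` defaults to 4 for a single-class model and 8 otherwise.
    ``tolerance`` is the relative log-likelihood change declaring
    convergence.  ``latent_corr`` is the starting (or, when
    ``estimate_latent_corr`` is False, fixed) trait-ERS correlation.
    """

    quad_points: int = 15
    n_starts: int | None = None
    tolerance: float = 1e-6
    max_iter: int = 2000
    seed: int | None = None
    estimate_latent_corr: bool = True
    latent_corr: float = 0.0
    omega_nonnegative: bool = False
    start_scale: float = 0.3
    min_n_warn: int = 200

    def resolved_starts(self, C: int) -> int:
        if self.n_starts is not None:
            return self.n_starts
        return 4 if C == 1 else 8


@dataclasses.dataclass
class FitResult:
    """Best Step-1 solution across random starts."""

    params: MixTreeParameters
    loglik: float
    n_starts: int
    converged: bool
    start_logliks: list[float]
    config: FitConfig
    n_persons: int
    monotone_violation: float = 0.0
    label_permutation: np.ndarray | None = None

    @property
    def n_classes(self) -> int:
        return self.params.n_classes

    def quadrature(self) -> QuadratureGrid:
        return QuadratureGrid(self.config.quad_points, self.params.latent_corr)


@dataclasses.dataclass
class LatentPosterior:
    """Per-person posterior over classes plus EAP scores."""

    class_post: np.ndarray
    assignment: np.ndarray
    eap: LatentScores

    def __post_init__(self) -> None:
        rows = self.class_post.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-8):
            raise ValueError("posterior rows must sum to 1")


@dataclasses.dataclass
class ClassificationError:
    """Modal-assignment error probabilities D[c, k] = P(w=k | X=c)."""

    D: np.ndarray
    total_error: float

    @property
    def mean_diag_accuracy(self) -> float:
        return float(np.mean(np.diag(self.D)))


@dataclasses.dataclass
class CovariateModel:
    """Multinomial-logistic model of class membership on covariates.

    The first class is the reference: its intercept and slopes are fixed at
    0.  ``se_*`` are observed-information standard errors (free parameters
    only; reference-class entries are 0).
    """

    gamma0: np.ndarray
    gamma: np.ndarray
    se_gamma0: np.ndarray
    se_gamma: np.ndarray
    loglik: float
    converged: bool

    @property
    def n_classes(self) -> int:
        return self.gamma0.shape[0]


@dataclasses.dataclass
class ThreeStepResult:
    posterior: LatentPosterior
    error: ClassificationError
    covariates: CovariateModel


# ---------------------------------------------------------------------------
# Parameter packing
# ---------------------------------------------------------------------------


class _Packer:
    """Maps between MixTreeParameters and the unconstrained vector."""

    def __init__(self, J: int, C: int, config: FitConfig):
        self.J, self.C, self.config = J, C, config
        self.n_free = 2 * J + C * (3 * J + 1) + (C - 1)
        if config.estimate_latent_corr:
            self.n_free += 1

    def pack(self, params: MixTreeParameters) -> np.ndarray:
        J, C = self.J, self.C
        parts = [np.log(params.alpha_trait), params.beta1]
        if self.config.omega_nonnegative:
            parts.append(np.log(np.maximum(params.omega, 1e-6)).ravel())
        else:
            parts.append(params.omega.ravel())
        parts += [
            np.log(params.alpha_ers),
            params.beta2.ravel(),
            params.beta3.ravel(),
            np.log(params.pi[1:] / params.pi[0]),
        ]
        if self.config.estimate_latent_corr:
            parts.append(np.array([np.arctanh(params.latent_corr)]))
        return np.concatenate(parts)

    def unpack(self, x: np.ndarray) -> MixTreeParameters:
        J, C = self.J, self.C
        i = 0
        alpha = np.exp(x[i : i + J]); i += J
        beta1 = x[i : i + J]; i += J
        omega = x[i : i + J * C].reshape(J, C); i += J * C
        if self.config.omega_nonnegative:
            omega = np.exp(omega)
        alpha_ers = np.exp(x[i : i + C]); i += C
        beta2 = x[i : i + J * C].reshape(J, C); i += J * C
        beta3 = x[i : i + J * C].reshape(J, C); i += J * C
        logits = np.concatenate([[0.0], x[i : i + C - 1]]); i += C - 1
        pi = softmax(logits)
        if self.config.estimate_latent_corr:
            # tanh saturates numerically when the data push the correlation
            # to the boundary; keep it inside the open interval
            corr = float(np.clip(np.tanh(x[i]), -0.9999, 0.9999)); i += 1
        else:
            corr = self.config.latent_corr
        return MixTreeParameters(
            alpha_trait=alpha, beta1=beta1.copy(), omega=omega,
            alpha_ers=alpha_ers, beta2=beta2, beta3=beta3, pi=pi,
            latent_corr=corr,
        )


# ---------------------------------------------------------------------------
# Step-1 objective with analytic gradient
# ---------------------------------------------------------------------------


class _Objective:
    """Negative mean marginal log-likelihood and its gradient.

    The forward pass evaluates conditional node log-likelihoods on the
    quadrature grid via masked matrix products; the backward pass reuses the
    joint posterior weights W[p, c, q], for which the score of every item
    parameter is a posterior-weighted Bernoulli residual.
    """

    def __init__(self, pseudo: PseudoItemMatrix, C: int, config: FitConfig):
        self.config = config
        self.C = C
        self.packer = _Packer(pseudo.n_items, C, config)
        self.N = pseudo.n_persons
        self.m1, self.m2, self.m3 = pseudo.m1, pseudo.m2, pseudo.m3
        self.Y1 = np.nan_to_num(pseudo.y1) * self.m1
        self.Y2 = np.nan_to_num(pseudo.y2) * self.m2
        self.Y3 = np.nan_to_num(pseudo.y3) * self.m3
        self.N1 = self.m1 - self.Y1
        self.N2 = self.m2 - self.Y2
        self.N3 = self.m3 - self.Y3
        base = QuadratureGrid(config.quad_points, 0.0)
        self.z1, self.z2, self.log_w = base.z1, base.z2, np.log(base.weights)

    def value_and_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        cfg = self.config
        p = self.packer.unpack(x)
        J, C, Q = p.n_items, self.C, self.z1.shape[0]
        rho = p.latent_corr
        s = np.sqrt(1.0 - rho**2)
        theta = self.z1
        eta = rho * self.z1 + s * self.z2

        a = p.alpha_trait[:, None]
        x1 = a * theta[None, :] + p.beta1[:, None]
        aw = (p.alpha_trait[:, None] * p.omega)[:, :, None]
        ers = p.alpha_ers[None, :, None] * eta[None, None, :]
        base = aw * theta[None, None, :]
        x2 = base - ers + p.beta2[:, :, None]
        x3 = base + ers + p.beta3[:, :, None]
        p1, p2, p3 = expit(x1), expit(x2), expit(x3)

        ll0 = self.Y1 @ log_expit(x1) + self.N1 @ log_expit(-x1)  # (N,Q)
        lw = np.empty((self.N, C, Q))
        for c in range(C):
            lw[:, c, :] = (
                ll0
                + self.Y2 @ log_expit(x2[:, c, :])
                + self.N2 @ log_expit(-x2[:, c, :])
                + self.Y3 @ log_expit(x3[:, c, :])
                + self.N3 @ log_expit(-x3[:, c, :])
            )
        lw += np.log(p.pi)[None, :, None] + self.log_w[None, None, :]
        ll = logsumexp(lw, axis=(1, 2))
        f = -float(ll.sum()) / self.N

        W = np.exp(lw - ll[:, None, None])  # (N,C,Q)
        V = W.sum(axis=1)  # (N,Q)
        R = W.sum(axis=2)  # (N,C)

        r1 = self.Y1.T @ V - p1 * (self.m1.T @ V)  # (J,Q)
        g_beta1 = r1.sum(axis=1)
        g_alpha = r1 @ theta
        g_omega = np.empty((J, C))
        g_beta2 = np.empty((J, C))
        g_beta3 = np.empty((J, C))
        g_aers = np.empty(C)
        g_rho_raw = 0.0
        deta = self.z1 - (rho / s) * self.z2 if cfg.estimate_latent_corr else None
        for c in range(C):
            Wc = W[:, c, :]
            B2 = self.m2.T @ Wc
            B3 = self.m3.T @ Wc
            r2 = self.Y2.T @ Wc - p2[:, c, :] * B2
            r3 = self.Y3.T @ Wc - p3[:, c, :] * B3
            g_beta2[:, c] = r2.sum(axis=1)
            g_beta3[:, c] = r3.sum(axis=1)
            st = (r2 + r3) @ theta
            g_omega[:, c] = p.alpha_trait * st
            g_alpha += p.omega[:, c] * st
            diff = r3 - r2
            g_aers[c] = float(diff.sum(axis=0) @ eta)
            if deta is not None:
                g_rho_raw += p.alpha_ers[c] * float(diff.sum(axis=0) @ deta)

        # chain rules for the transformed parameters
        g_log_alpha = g_alpha * p.alpha_trait
        g_log_aers = g_aers * p.alpha_ers
        if cfg.omega_nonnegative:
            g_omega = g_omega * p.omega
        g_logits = (R - p.pi[None, :]).sum(axis=0)[1:]

        parts = [
            g_log_alpha, g_beta1, g_omega.ravel(), g_log_aers,
            g_beta2.ravel(), g_beta3.ravel(), g_logits,
        ]
        if cfg.estimate_latent_corr:
            parts.append(np.array([g_rho_raw * (1.0 - rho**2)]))
        grad = -np.concatenate(parts) / self.N
        return f, grad


# ---------------------------------------------------------------------------
# Starting values
# ---------------------------------------------------------------------------


def _logit_mean(y: np.ndarray, m: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(m.sum(0) > 0, y.sum(0) / np.maximum(m.sum(0), 1.0), 0.5)
    p = np.clip(p, 0.05, 0.95)
    return np.log(p / (1 - p))


def _heuristic_params(pseudo: PseudoItemMatrix, C: int, corr: float) -> MixTreeParameters:
    J = pseudo.n_items
    m1, m2, m3 = pseudo.m1, pseudo.m2, pseudo.m3
    beta1 = _logit_mean(np.nan_to_num(pseudo.y1) * m1, m1)
    beta2 = _logit_mean(np.nan_to_num(pseudo.y2) * m2, m2)
    beta3 = _logit_mean(np.nan_to_num(pseudo.y3) * m3, m3)
    # spread the class-specific weights so starts are not symmetric in labels
    offs = np.linspace(0.25, -0.25, C) if C > 1 else np.zeros(1)
    return MixTreeParameters(
        alpha_trait=np.ones(J),
        beta1=beta1,
        omega=np.tile(0.6 + offs, (J, 1)),
        alpha_ers=0.6 - offs,
        beta2=np.tile(beta2[:, None], (1, C)),
        beta3=np.tile(beta3[:, None], (1, C)),
        pi=np.full(C, 1.0 / C),
        latent_corr=corr,
    )


def _perturb(x: np.ndarray, packer: _Packer, rng: np.random.Generator,
             scale: float) -> np.ndarray:
    noise = rng.normal(0.0, scale, size=x.shape)
    if packer.config.estimate_latent_corr:
        noise[-1] *= 0.2  # keep the correlation start near its anchor
    return x + noise


# ---------------------------------------------------------------------------
# Step 1
# ---------------------------------------------------------------------------


def fit_step1(
    responses: ResponseMatrix | np.ndarray,
    C: int,
    config: FitConfig | None = None,
) -> FitResult:
    """Marginal ML fit of the C-class MixTree (Step 1).

    Runs ``n_starts`` optimizations from perturbed warm starts (for C > 1
    the anchor is a converged single-class fit expanded to C classes) and
    returns the solution with the largest log-likelihood, classes reordered
    to the canonical descending-ERS-loading convention.

    Raises
    ------
    RuntimeError
        If no start converges; the exception message carries per-start
        diagnostics.
    """
    if config is None:
        config = FitConfig()
    if C < 1:
        raise ValueError("C must be >= 1")
    if not isinstance(responses, ResponseMatrix):
        responses = ResponseMatrix(np.asarray(responses, dtype=float))
    if responses.n_persons < config.min_n_warn:
        warnings.warn(
            f"N={responses.n_persons} respondents is small for mixture "
            "estimation; results may be unstable",
            stacklevel=2,
        )
    pseudo = decompose_to_pseudo_items(responses)
    rng = np.random.default_rng(config.seed)
    n_starts = config.resolved_starts(C)

    anchor = _anchor_start(pseudo, C, config, rng)
    obj = _Objective(pseudo, C, config)
    x_anchor = obj.packer.pack(anchor)

    start_logliks: list[float] = []
    best = None
    worst_violation = 0.0
    diagnostics = []
    for start in range(n_starts):
        x0 = x_anchor if start == 0 else _perturb(x_anchor, obj.packer, rng,
                                                  config.start_scale)
        res, violation = _run_lbfgs(obj, x0, config)
        loglik = -res.fun * obj.N
        start_logliks.append(float(loglik))
        worst_violation = max(worst_violation, violation)
        diagnostics.append((start, res.success, res.message))
        if res.success and (best is None or loglik > best[0]):
            best = (float(loglik), res.x)

    if best is None:
        raise RuntimeError(
            "no Step-1 start converged; per-start diagnostics: "
            + "; ".join(f"start {s}: {msg}" for s, _, msg in diagnostics)
        )
    if worst_violation > 1e-8:
        logger.warning(
            "monitored log-likelihood decreased by %.3g during optimization",
            worst_violation,
        )

    params = obj.packer.unpack(best[1])
    perm = params.canonical_permutation()
    params = params.permute_classes(perm)
    return FitResult(
        params=params,
        loglik=best[0],
        n_starts=n_starts,
        converged=True,
        start_logliks=start_logliks,
        config=config,
        n_persons=responses.n_persons,
        monotone_violation=worst_violation,
        label_permutation=perm,
    )


def _anchor_start(
    pseudo: PseudoItemMatrix, C: int, config: FitConfig,
    rng: np.random.Generator,
) -> MixTreeParameters:
    """Warm anchor: for C > 1, expand a converged single-class fit."""
    if C == 1:
        return _heuristic_params(pseudo, 1, config.latent_corr)
    cfg1 = dataclasses.replace(config, n_starts=1)
    obj1 = _Objective(pseudo, 1, cfg1)
    x0 = obj1.packer.pack(_heuristic_params(pseudo, 1, cfg1.latent_corr))
    res, _ = _run_lbfgs(obj1, x0, cfg1)
    base = obj1.packer.unpack(res.x)
    offs = np.linspace(0.25, -0.25, C)
    return MixTreeParameters(
        alpha_trait=base.alpha_trait,
        beta1=base.beta1,
        omega=base.omega[:, [0] * C] + offs[None, :],
        alpha_ers=np.maximum(base.alpha_ers[0] - offs, 0.05),
        beta2=base.beta2[:, [0] * C],
        beta3=base.beta3[:, [0] * C],
        pi=np.full(C, 1.0 / C),
        latent_corr=base.latent_corr,
    )


def _run_lbfgs(obj: _Objective, x0: np.ndarray, config: FitConfig):
    trajectory: list[float] = []
    last: dict = {}

    def fun(x):
        f, g = obj.value_and_grad(x)
        last["x"], last["f"] = x.copy(), f
        return f, g

    def callback(xk):
        # the accepted iterate was the most recent function evaluation
        if "x" in last and np.array_equal(last["x"], xk):
            trajectory.append(last["f"])

    res = minimize(
        fun,
        x0,
        jac=True,
        callback=callback,
        method="L-BFGS-B",
        options={
            "maxiter": config.max_iter,
            "ftol": config.tolerance * 1e-2,
            "gtol": 1e-5,
            "maxcor": 20,
        },
    )
    violation = 0.0
    if len(trajectory) > 1:
        diffs = np.diff(trajectory)
        violation = float(max(0.0, diffs.max()))
    return res, violation


# ---------------------------------------------------------------------------
# Step 2
# ---------------------------------------------------------------------------


def eap_scores(
    fit: FitResult,
    responses: ResponseMatrix | np.ndarray,
    quadrature: QuadratureGrid | None = None,
) -> LatentScores:
    """EAP trait/ERS scores with posterior-SD standard errors.

    Posterior means and SDs are marginal over classes and quadrature nodes
    under the fitted mixture.
    """
    if not isinstance(responses, ResponseMatrix):
        responses = ResponseMatrix(np.asarray(responses, dtype=float))
    if quadrature is None:
        quadrature = fit.quadrature()
    pseudo = decompose_to_pseudo_items(responses)
    W, _ = posterior_weights(fit.params, pseudo, quadrature)
    Wq = W.sum(axis=1)  # (N,Q)
    theta = Wq @ quadrature.theta
    eta = Wq @ quadrature.eta
    var_theta = Wq @ quadrature.theta**2 - theta**2
    var_eta = Wq @ quadrature.eta**2 - eta**2
    tiny = 1e-12
    return LatentScores(
        theta=theta,
        eta=eta,
        se_theta=np.sqrt(np.maximum(var_theta, tiny)),
        se_eta=np.sqrt(np.maximum(var_eta, tiny)),
    )


def posterior_class_probs(
    fit: FitResult,
    responses: ResponseMatrix | np.ndarray,
    quadrature: QuadratureGrid | None = None,
) -> LatentPosterior:
    """Posterior class memberships (Bayes' rule over the fitted mixture)."""
    if not isinstance(responses, ResponseMatrix):
        responses = ResponseMatrix(np.asarray(responses, dtype=float))
    if quadrature is None:
        quadrature = fit.quadrature()
    pseudo = decompose_to_pseudo_items(responses)
    W, _ = posterior_weights(fit.params, pseudo, quadrature)
    class_post = W.sum(axis=2)
    class_post /= class_post.sum(axis=1, keepdims=True)
    Wq = W.sum(axis=1)
    theta = Wq @ quadrature.theta
    eta = Wq @ quadrature.eta
    tiny = 1e-12
    eap = LatentScores(
        theta=theta,
        eta=eta,
        se_theta=np.sqrt(np.maximum(Wq @ quadrature.theta**2 - theta**2, tiny)),
        se_eta=np.sqrt(np.maximum(Wq @ quadrature.eta**2 - eta**2, tiny)),
    )
    return LatentPosterior(
        class_post=class_post,
        assignment=modal_assign(class_post),
        eap=eap,
    )


def modal_assign(posterior: np.ndarray) -> np.ndarray:
    """Assign each respondent to the class with the largest posterior.

    Ties are broken toward the lowest class index and logged.
    """
    posterior = np.asarray(posterior, dtype=float)
    assignment = np.argmax(posterior, axis=1)
    top = posterior[np.arange(posterior.shape[0]), assignment]
    ties = (posterior == top[:, None]).sum(axis=1) > 1
    if np.any(ties):
        logger.info(
            "modal assignment ties for %d respondent(s); broke toward the "
            "lowest class index", int(ties.sum()),
        )
    return assignment


def classification_error(
    posterior: np.ndarray,
    assignment: np.ndarray,
    pi: np.ndarray | None = None,
) -> ClassificationError:
    """Classification-error matrix D[c, k] = P(w=k | X=c).

    ``D[c, k] = (1/N) sum_p post[p, c] 1[w_p = k] / P(X=c)``.  By default
    ``P(X=c)`` is the mean posterior probability, which coincides with the
    fitted class proportion at the Step-1 MLE and makes the rows sum to 1
    exactly; a user-supplied ``pi`` is used instead when given.
    """
    posterior = np.asarray(posterior, dtype=float)
    assignment = np.asarray(assignment, dtype=int)
    N, C = posterior.shape
    if assignment.shape[0] != N:
        raise ValueError("assignment length must match the posterior rows")
    marginal = posterior.mean(axis=0) if pi is None else np.asarray(pi, dtype=float)
    empty = np.nonzero(marginal <= 0)[0]
    if empty.size:
        raise ValueError(f"class {empty[0] + 1} has probability zero")
    ind = np.zeros((N, C))
    ind[np.arange(N), assignment] = 1.0
    D = (posterior.T @ ind) / (N * marginal[:, None])
    total = float(np.sum(marginal[:, None] * D * (1 - np.eye(C))))
    return ClassificationError(D=D, total_error=total)


# ---------------------------------------------------------------------------
# Step 3
# ---------------------------------------------------------------------------


def _step3_loglik_grad(
    x: np.ndarray, Z1: np.ndarray, D: np.ndarray, w: np.ndarray
) -> tuple[float, np.ndarray]:
    """Negative log-likelihood and gradient of the corrected covariate model.

    ``P(w_p = k | Z_p) = sum_c P(X=c | Z_p; gamma) D[c, k]`` with D fixed.
    ``Z1`` carries an intercept column; ``x`` holds the (T+1) x (C-1) free
    coefficients (first class is the reference).
    """
    N, T1 = Z1.shape
    C = D.shape[0]
    G = np.concatenate([np.zeros((T1, 1)), x.reshape(T1, C - 1)], axis=1)
    P = softmax(Z1 @ G, axis=1)  # (N,C)
    Dw = D[:, w].T  # (N,C): D[c, w_p]
    mix = P * Dw
    denom = mix.sum(axis=1)
    nll = -float(np.log(denom).sum())
    q = mix / denom[:, None]
    grad_G = Z1.T @ (q - P)  # (T1,C)
    return nll, -grad_G[:, 1:].ravel()


def fit_step3(
    assignment: np.ndarray,
    D: ClassificationError | np.ndarray,
    covariates: np.ndarray,
    max_iter: int = 500,
) -> CovariateModel:
    """Classification-error-corrected covariate regression (Step 3).

    Treats the modal assignment as a single error-prone indicator of the
    true class with fixed conditional probabilities ``D`` and models the
    true class by multinomial logistic regression on the covariates.  With
    ``D`` equal to the identity this reduces to an ordinary multinomial
    logit of the assignments on the covariates.  Standard errors come from
    the observed information (finite differences of the analytic gradient)
    and do not propagate Step-1 sampling error.
    """
    Dmat = D.D if isinstance(D, ClassificationError) else np.asarray(D, dtype=float)
    if not np.allclose(Dmat.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("classification-error matrix rows must sum to 1")
    Z = np.asarray(covariates, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("covariate matrix is singular")
    w = np.asarray(assignment, dtype=int)
    C = Dmat.shape[0]
    N, T = Z.shape
    Z1 = np.concatenate([np.ones((N, 1)), Z], axis=1)
    x0 = np.zeros((T + 1) * (C - 1))
    res = minimize(
        _step3_loglik_grad, x0, args=(Z1, Dmat, w), jac=True,
        method="L-BFGS-B", options={"maxiter": max_iter, "ftol": 1e-12},
    )
    G = np.concatenate([np.zeros((T + 1, 1)), res.x.reshape(T + 1, C - 1)], axis=1)
    if np.abs(G).max() > 10:
        warnings.warn(
            "very large covariate coefficients suggest (quasi-)separation; "
            "estimates may be unbounded", stacklevel=2,
        )
    H = _fd_hessian(lambda x: _step3_loglik_grad(x, Z1, Dmat, w)[1], res.x)
    se = np.full_like(res.x, np.nan)
    try:
        cov = np.linalg.inv(0.5 * (H + H.T))
        diag = np.diag(cov)
        if np.all(diag > 0):
            se = np.sqrt(diag)
    except np.linalg.LinAlgError:
        warnings.warn("singular information matrix; standard errors unavailable",
                      stacklevel=2)
    SE = np.concatenate([np.zeros((T + 1, 1)), se.reshape(T + 1, C - 1)], axis=1)
    return CovariateModel(
        gamma0=G[0], gamma=G[1:], se_gamma0=SE[0], se_gamma=SE[1:],
        loglik=-float(res.fun), converged=bool(res.success),
    )


def _fd_hessian(grad_fn, x: np.ndarray, step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian from an analytic gradient."""
    n = x.shape[0]
    H = np.empty((n, n))
    for i in range(n):
        e = np.zeros(n)
        e[i] = step
        H[i] = (grad_fn(x + e) - grad_fn(x - e)) / (2 * step)
    return 0.5 * (H + H.T)


def predict_class_probs(model: CovariateModel, covariates: np.ndarray) -> np.ndarray:
    """Class-membership probabilities for covariate row(s)."""
    Z = np.atleast_2d(np.asarray(covariates, dtype=float))
    lin = model.gamma0[None, :] + Z @ model.gamma
    out = softmax(lin, axis=1)
    return out[0] if np.asarray(covariates).ndim == 1 else out


# ---------------------------------------------------------------------------
# Label alignment
# ---------------------------------------------------------------------------


def align_labels(
    reference: MixTreeParameters, candidate: MixTreeParameters
) -> tuple[MixTreeParameters, np.ndarray]:
    """Relabel ``candidate`` classes to best match ``reference``.

    Searches all C! permutations for the one minimizing the total squared
    distance between the class-specific parameter blocks (omega, ERS
    loadings, both extremity intercept sets).  Returns the relabeled
    candidate and the permutation (new position -> old candidate label).
    """
    C = reference.n_classes
    if candidate.n_classes != C:
        raise ValueError("reference and candidate must have equal C")
    blocks_ref = np.concatenate(
        [reference.omega, reference.alpha_ers[None, :], reference.beta2,
         reference.beta3], axis=0,
    )
    blocks_cand = np.concatenate(
        [candidate.omega, candidate.alpha_ers[None, :], candidate.beta2,
         candidate.beta3], axis=0,
    )
    best_perm, best_cost = None, np.inf
    for perm in itertools.permutations(range(C)):
        cost = float(np.sum((blocks_ref - blocks_cand[:, perm]) ** 2))
        if cost < best_cost:
            best_cost, best_perm = cost, np.asarray(perm)
    return candidate.permute_classes(best_perm), best_perm
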