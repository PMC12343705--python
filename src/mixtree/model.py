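"""Core MixTree model: pseudo-item decomposition and response probabilities.

A four-point rating response is viewed as the outcome of a small decision
tree.  The first (direction) node decides disagreement vs. agreement and is
driven by the substantive trait :math:`\\theta` alone.  Conditional on the
direction, an extremity node decides between the mild and the extreme
category and is driven by both the trait and an extreme-response-style (ERS)
factor :math:`\\eta`.  Each node is a 2-PL style Bernoulli item:

.. math::

    P(y^*_{1pj}=1) &= \\sigma(\\alpha^{(trait)}_j \\theta_p + \\beta_{1j}) \\\\
    P(y^*_{2pj}=1 \\mid X=c) &= \\sigma(\\alpha^{(trait)}_j \\omega_{jc}
        \\theta_p - \\alpha^{(ers)}_c \\eta_p + \\beta_{2jc}) \\\\
    P(y^*_{3pj}=1 \\mid X=c) &= \\sigma(\\alpha^{(trait)}_j \\omega_{jc}
        \\theta_p + \\alpha^{(ers)}_c \\eta_p + \\beta_{3jc})

where :math:`\\sigma` is the logistic function and :math:`X` a latent class.
Classes differ in the proportionality constants :math:`\\omega_{jc}` (how much
the trait carries over from the direction to the extremity decision), the
item-invariant ERS loadings :math:`\\alpha^{(ers)}_c`, and the extremity
intercepts, letting subpopulations weight trait and response style
differently.  The direction node is class-invariant, which anchors the trait
metric across classes.  The single-class model (C=1) is the traditional
IRTree.

Latent scores are standard bivariate normal (means 0, variances 1,
class-invariant correlation) for identification; integrals over them are
evaluated on a Gauss-Hermite product grid.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable

import numpy as np
from scipy.special import expit, log_expit, logsumexp

__all__ = [
    "ResponseMatrix",
    "PseudoItemMatrix",
    "MixTreeParameters",
    "LatentScores",
    "QuadratureGrid",
    "decompose_to_pseudo_items",
    "recompose_responses",
    "node_probabilities",
    "category_probabilities",
    "person_loglik_given_class",
    "marginal_person_loglik",
    "marginal_loglik",
    "posterior_weights",
    "count_parameters",
]

CATEGORIES = (1, 2, 3, 4)

#: Pseudo-item coding for four-point items.  Rows: category 1..4.
#: Columns: (y1, y2, y3); None marks missing-by-design (a respondent taking
#: the agreement branch never faces the disagreement-extremity decision and
#: vice versa).
PSEUDO_ITEM_CODING = {
    1: (0, 0, None),
    2: (0, 1, None),
    3: (1, None, 0),
    4: (1, None, 1),
}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ResponseMatrix:
    """N x J matrix of rating responses in {1, 2, 3, 4}.

    Parameters
    ----------
    values
        Float array; missing responses are ``NaN``.  Integer input is
        converted.  Persons are rows, items columns.
    item_names
        Optional item labels (defaults to ``item1..itemJ``).
    """

    values: np.ndarray
    item_names: list[str] | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] < 1 or values.shape[1] < 1:
            raise ValueError("responses must be a non-empty 2-D matrix")
        observed = ~np.isnan(values)
        valid = np.isin(values[observed], CATEGORIES)
        if not np.all(valid):
            rows, cols = np.nonzero(observed)
            bad = np.nonzero(~valid)[0][0]
            r, c = rows[bad], cols[bad]
            raise ValueError(
                f"response at row {r + 1}, column {c + 1} is {values[r, c]:g}; "
                "responses must be in {1, 2, 3, 4} or missing"
            )
        self.values = values
        if self.item_names is None:
            self.item_names = [f"item{j + 1}" for j in range(values.shape[1])]
        elif len(self.item_names) != values.shape[1]:
            raise ValueError("item_names length does not match column count")

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]


@dataclasses.dataclass
class PseudoItemMatrix:
    """Binary pseudo-item decomposition of a response matrix.

    ``y1`` (direction), ``y2`` (disagreement extremity), ``y3`` (agreement
    extremity) are N x J arrays with ``NaN`` where the node is missing by
    design (or the original response was missing).  ``m1``/``m2``/``m3`` are
    the corresponding 0/1 observation masks.
    """

    y1: np.ndarray
    y2: np.ndarray
    y3: np.ndarray

    def __post_init__(self) -> None:
        for name in ("y1", "y2", "y3"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
        if not (self.y1.shape == self.y2.shape == self.y3.shape):
            raise ValueError("pseudo-item arrays must share one shape")

    @property
    def m1(self) -> np.ndarray:
        return (~np.isnan(self.y1)).astype(float)

    @property
    def m2(self) -> np.ndarray:
        return (~np.isnan(self.y2)).astype(float)

    @property
    def m3(self) -> np.ndarray:
        return (~np.isnan(self.y3)).astype(float)

    @property
    def n_persons(self) -> int:
        return self.y1.shape[0]

    @property
    def n_items(self) -> int:
        return self.y1.shape[1]


@dataclasses.dataclass
class MixTreeParameters:
    """Full parameter set of a C-class MixTree for J items.

    Attributes
    ----------
    alpha_trait : (J,) positive trait loadings at the direction node.
    beta1 : (J,) direction-node intercepts.
    omega : (J, C) class-specific proportionality constants.
    alpha_ers : (C,) item-invariant, class-specific ERS loadings.
    beta2, beta3 : (J, C) extremity-node intercepts.
    pi : (C,) unconditional class proportions (positive, sums to 1).
    latent_corr : trait-ERS correlation, class-invariant, in (-1, 1).

    Latent means are fixed at 0 and variances at 1 in every class.
    """

    alpha_trait: np.ndarray
    beta1: np.ndarray
    omega: np.ndarray
    alpha_ers: np.ndarray
    beta2: np.ndarray
    beta3: np.ndarray
    pi: np.ndarray
    latent_corr: float = 0.0

    def __post_init__(self) -> None:
        self.alpha_trait = np.atleast_1d(np.asarray(self.alpha_trait, dtype=float))
        self.beta1 = np.atleast_1d(np.asarray(self.beta1, dtype=float))
        self.alpha_ers = np.atleast_1d(np.asarray(self.alpha_ers, dtype=float))
        self.pi = np.atleast_1d(np.asarray(self.pi, dtype=float))
        J = self.alpha_trait.shape[0]
        C = self.pi.shape[0]
        for name in ("omega", "beta2", "beta3"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr.reshape(J, C))
        if self.alpha_ers.shape[0] != C:
            raise ValueError("alpha_ers must have one entry per class")
        if not np.all(self.pi > 0) or abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must be a strictly positive simplex")
        if not -1.0 < self.latent_corr < 1.0:
            raise ValueError("latent_corr must lie in (-1, 1)")

    @property
    def n_classes(self) -> int:
        return self.pi.shape[0]

    @property
    def n_items(self) -> int:
        return self.alpha_trait.shape[0]

    def permute_classes(self, perm: Iterable[int]) -> "MixTreeParameters":
        """Return a copy with classes reordered by ``perm`` (new <- old)."""
        perm = np.asarray(list(perm), dtype=int)
        if sorted(perm.tolist()) != list(range(self.n_classes)):
            raise ValueError("perm must be a permutation of class indices")
        return MixTreeParameters(
            alpha_trait=self.alpha_trait.copy(),
            beta1=self.beta1.copy(),
            omega=self.omega[:, perm],
            alpha_ers=self.alpha_ers[perm],
            beta2=self.beta2[:, perm],
            beta3=self.beta3[:, perm],
            pi=self.pi[perm],
            latent_corr=self.latent_corr,
        )

    def canonical_permutation(self) -> np.ndarray:
        """Reporting order: classes sorted by descending ERS loading.

        Mixture class labels are arbitrary; sorting by the ERS loading puts
        the most heuristic-driven (satisficing-like) class first.
        """
        return np.argsort(-self.alpha_ers, kind="stable")


@dataclasses.dataclass
class LatentScores:
    """EAP trait/ERS scores with posterior-SD standard errors."""

    theta: np.ndarray
    eta: np.ndarray
    se_theta: np.ndarray | None = None
    se_eta: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        for name in ("se_theta", "se_eta"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if np.any(arr <= 0):
                    raise ValueError(f"{name} entries must be positive")
                setattr(self, name, arr)


class QuadratureGrid:
    """Gauss-Hermite product grid for the bivariate standard-normal prior.

    Nodes of the probabilists' Gauss-Hermite rule are laid out on a Q x Q
    product grid over independent standard normals ``(z1, z2)`` and rotated
    by the Cholesky factor of the latent correlation matrix, so that
    ``theta = z1`` and ``eta = corr * z1 + sqrt(1 - corr**2) * z2``.
    Weights are normalized to sum to 1.
    """

    def __init__(self, n_points: int = 15, corr: float = 0.0):
        if n_points < 2:
            raise ValueError("need at least 2 quadrature points per dimension")
        if not -1.0 < corr < 1.0:
            raise ValueError("corr must lie in (-1, 1)")
        nodes, weights = np.polynomial.hermite_e.hermegauss(n_points)
        weights = weights / weights.sum()
        self.n_points = n_points
        self.corr = float(corr)
        z1, z2 = np.meshgrid(nodes, nodes, indexing="ij")
        self.z1 = z1.ravel()
        self.z2 = z2.ravel()
        w1, w2 = np.meshgrid(weights, weights, indexing="ij")
        self.weights = (w1 * w2).ravel()
        self.theta = self.z1
        self.eta = corr * self.z1 + math.sqrt(1.0 - corr**2) * self.z2

    def with_corr(self, corr: float) -> "QuadratureGrid":
        if corr == self.corr:
            return self
        return QuadratureGrid(self.n_points, corr)

    @property
    def size(self) -> int:
        return self.theta.shape[0]


# ---------------------------------------------------------------------------
# Pseudo-item decomposition
# ---------------------------------------------------------------------------


def decompose_to_pseudo_items(responses: ResponseMatrix | np.ndarray) -> PseudoItemMatrix:
    """Decompose 1-4 responses into the three binary tree nodes.

    Category 1 -> (0, 0, -), 2 -> (0, 1, -), 3 -> (1, -, 0), 4 -> (1, -, 1),
    where '-' is missing-by-design.  A missing response yields all three
    nodes missing.
    """
    if not isinstance(responses, ResponseMatrix):
        responses = ResponseMatrix(np.asarray(responses))
    vals = responses.values
    y1 = np.where(np.isnan(vals), np.nan, (vals >= 3).astype(float))
    y2 = np.where(vals <= 2, (vals == 2).astype(float), np.nan)
    y3 = np.where(vals >= 3, (vals == 4).astype(float), np.nan)
    return PseudoItemMatrix(y1=y1, y2=y2, y3=y3)


def recompose_responses(pseudo: PseudoItemMatrix) -> np.ndarray:
    """Invert the pseudo-item decomposition back to categories 1-4."""
    y1, y2, y3 = pseudo.y1, pseudo.y2, pseudo.y3
    out = np.full(y1.shape, np.nan)
    out[(y1 == 0) & (y2 == 0)] = 1
    out[(y1 == 0) & (y2 == 1)] = 2
    out[(y1 == 1) & (y3 == 0)] = 3
    out[(y1 == 1) & (y3 == 1)] = 4
    return out


# ---------------------------------------------------------------------------
# Probabilities
# ---------------------------------------------------------------------------


def _linear_predictors(
    params: MixTreeParameters, theta: np.ndarray, eta: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Node linear predictors on a latent grid.

    Returns ``x1`` with shape (J, Q) and ``x2``, ``x3`` with shape (J, C, Q)
    for ``theta``/``eta`` of shape (Q,).
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    a = params.alpha_trait[:, None]
    x1 = a * theta[None, :] + params.beta1[:, None]
    aw = (params.alpha_trait[:, None] * params.omega)[:, :, None]  # (J,C,1)
    ers = params.alpha_ers[None, :, None] * eta[None, None, :]
    base = aw * theta[None, None, :]
    x2 = base - ers + params.beta2[:, :, None]
    x3 = base + ers + params.beta3[:, :, None]
    return x1, x2, x3


def node_probabilities(
    params: MixTreeParameters,
    theta: float,
    eta: float,
    item: int,
    class_id: int,
) -> tuple[float, float, float]:
    """Endorsement probabilities (p1, p2, p3) of the three tree nodes.

    ``p1`` uses the class-invariant direction parameters; ``p2`` carries the
    negative ERS sign (high ERS pushes toward the extreme disagreement
    category 1), ``p3`` the positive sign.
    """
    J, C = params.n_items, params.n_classes
    if not 0 <= item < J:
        raise IndexError(f"item {item} out of range for J={J}")
    if not 0 <= class_id < C:
        raise IndexError(f"class {class_id} out of range for C={C}")
    x1, x2, x3 = _linear_predictors(params, np.array([theta]), np.array([eta]))
    return (
        float(expit(x1[item, 0])),
        float(expit(x2[item, class_id, 0])),
        float(expit(x3[item, class_id, 0])),
    )


def category_probabilities(
    params: MixTreeParameters,
    theta: float,
    eta: float,
    item: int,
    class_id: int,
) -> np.ndarray:
    """Probabilities of the four rating categories given class membership.

    Composition over the tree: P(1) = (1-p1)(1-p2), P(2) = (1-p1)p2,
    P(3) = p1(1-p3), P(4) = p1*p3; sums to 1 by construction.
    """
    p1, p2, p3 = node_probabilities(params, theta, eta, item, class_id)
    return np.array(
        [(1 - p1) * (1 - p2), (1 - p1) * p2, p1 * (1 - p3), p1 * p3]
    )


def category_probability_grid(
    params: MixTreeParameters, theta: np.ndarray, eta: np.ndarray
) -> np.ndarray:
    """Category probabilities on a latent grid, shape (J, C, Q, 4)."""
    x1, x2, x3 = _linear_predictors(params, theta, eta)
    p1 = expit(x1)[:, None, :]
    p2 = expit(x2)
    p3 = expit(x3)
    return np.stack(
        [(1 - p1) * (1 - p2), (1 - p1) * p2, p1 * (1 - p3), p1 * p3], axis=-1
    )


def person_loglik_given_class(
    params: MixTreeParameters,
    pseudo: PseudoItemMatrix,
    person: int,
    theta: float,
    eta: float,
    class_id: int,
) -> float:
    """Log-likelihood of one person's pseudo-items at fixed latent scores.

    Sums Bernoulli log-likelihoods over the observed nodes of all items;
    nodes that are missing by design contribute nothing.
    """
    ll = _loglik_pcq(
        params,
        _person_slice(pseudo, person),
        np.array([theta]),
        np.array([eta]),
    )
    return float(ll[0, class_id, 0])


def _person_slice(pseudo: PseudoItemMatrix, person: int) -> PseudoItemMatrix:
    return PseudoItemMatrix(
        y1=pseudo.y1[person : person + 1],
        y2=pseudo.y2[person : person + 1],
        y3=pseudo.y3[person : person + 1],
    )


def _loglik_pcq(
    params: MixTreeParameters,
    pseudo: PseudoItemMatrix,
    theta: np.ndarray,
    eta: np.ndarray,
) -> np.ndarray:
    """Conditional log-likelihood array of shape (N, C, Q).

    Entry (p, c, q) is ``log P(pseudo items of person p | X=c, grid node q)``.
    Computed with masked matrix products so cost scales as N*J*Q per class.
    """
    x1, x2, x3 = _linear_predictors(params, theta, eta)
    l1, l1c = log_expit(x1), log_expit(-x1)  # (J,Q)
    l2, l2c = log_expit(x2), log_expit(-x2)  # (J,C,Q)
    l3, l3c = log_expit(x3), log_expit(-x3)

    m1, m2, m3 = pseudo.m1, pseudo.m2, pseudo.m3
    y1 = np.nan_to_num(pseudo.y1) * m1
    y2 = np.nan_to_num(pseudo.y2) * m2
    y3 = np.nan_to_num(pseudo.y3) * m3

    base = y1 @ l1 + (m1 - y1) @ l1c  # (N,Q), class-invariant node
    C = params.n_classes
    out = np.empty((pseudo.n_persons, C, theta.shape[0]))
    for c in range(C):
        out[:, c, :] = (
            base
            + y2 @ l2[:, c, :]
            + (m2 - y2) @ l2c[:, c, :]
            + y3 @ l3[:, c, :]
            + (m3 - y3) @ l3c[:, c, :]
        )
    return out


def marginal_loglik(
    params: MixTreeParameters,
    pseudo: PseudoItemMatrix,
    grid: QuadratureGrid | None = None,
) -> np.ndarray:
    """Marginal log-likelihood per person, integrating classes and scores.

    ``log sum_c pi_c sum_q w_q P(Y_p | X=c, theta_q, eta_q)`` evaluated with
    log-sum-exp, so the result is finite whenever any node likelihood is
    positive.
    """
    if grid is None:
        grid = QuadratureGrid(15, params.latent_corr)
    ll = _loglik_pcq(params, pseudo, grid.theta, grid.eta)
    ll = ll + np.log(params.pi)[None, :, None] + np.log(grid.weights)[None, None, :]
    return logsumexp(ll, axis=(1, 2))


def marginal_person_loglik(
    params: MixTreeParameters,
    pseudo: PseudoItemMatrix,
    person: int,
    quadrature: QuadratureGrid | None = None,
) -> float:
    """Marginal log-likelihood of a single person."""
    return float(marginal_loglik(params, _person_slice(pseudo, person), quadrature)[0])


def posterior_weights(
    params: MixTreeParameters,
    pseudo: PseudoItemMatrix,
    grid: QuadratureGrid,
) -> tuple[np.ndarray, np.ndarray]:
    """Joint posterior over (class, grid node) per person.

    Returns ``(W, ll)`` where ``W`` has shape (N, C, Q) with rows summing to
    1 over (C, Q), and ``ll`` is the per-person marginal log-likelihood.
    ``W`` is the workhorse behind EAP scores, class posteriors, and the
    score equations of the marginal ML fit.
    """
    lw = _loglik_pcq(params, pseudo, grid.theta, grid.eta)
    lw += np.log(params.pi)[None, :, None] + np.log(grid.weights)[None, None, :]
    ll = logsumexp(lw, axis=(1, 2))
    W = np.exp(lw - ll[:, None, None])
    return W, ll


# ---------------------------------------------------------------------------
# Parameter bookkeeping
# ---------------------------------------------------------------------------


def count_parameters(C: int, J: int) -> tuple[int, int, int]:
    """Free-parameter counts ``(n_k, n_k0, n_kc)`` of a C-class model.

    Class-invariant: ``n_k0 = 2J + 1 + (C - 1)`` (direction loadings and
    intercepts, the latent correlation, and C-1 free class proportions).
    Class-specific: ``n_kc = C (3J + 1)`` (omega, both extremity intercept
    sets, and the ERS loading per class).
    """
    if C < 1 or J < 1:
        raise ValueError("C and J must be positive integers")
    n_k0 = 2 * J + 1 + (C - 1)
    n_kc = C * (3 * J + 1)
    return n_k0 + n_kc, n_k0, n_kc
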