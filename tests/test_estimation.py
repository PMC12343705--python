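"""Tests for the three-step estimation machinery."""

import numpy as np
import pytest
from scipy.optimize import approx_fprime
from scipy.special import expit

from mixtree.estimation import (
    FitConfig,
    _heuristic_params,
    _Objective,
    align_labels,
    classification_error,
    eap_scores,
    fit_step1,
    fit_step3,
    modal_assign,
    posterior_class_probs,
    predict_class_probs,
)
from mixtree.model import (
    MixTreeParameters,
    decompose_to_pseudo_items,
)
from mixtree.simulation import (
    SimulationDesign,
    evaluate_recovery,
    generate_dataset,
)


# ---------------------------------------------------------------------------
# Step-1 objective
# ---------------------------------------------------------------------------


class TestObjective:
    def test_analytic_gradient_matches_finite_differences(self):
        design = SimulationDesign(
            C_true=2, class_size_profile="equal", N=60, J=4, separation="high"
        )
        data = generate_dataset(design, seed=1)
        pseudo = decompose_to_pseudo_items(data.responses)
        cfg = FitConfig(quad_points=5)
        obj = _Objective(pseudo, 2, cfg)
        rng = np.random.default_rng(0)
        x0 = obj.packer.pack(_heuristic_params(pseudo, 2, 0.1))
        x0 += rng.normal(0, 0.1, x0.shape)
        _, grad = obj.value_and_grad(x0)
        grad_num = approx_fprime(
            x0, lambda x: obj.value_and_grad(x)[0], 1e-6
        )
        assert np.abs(grad - grad_num).max() < 1e-5

    def test_objective_agrees_with_model_marginal_loglik(self):
        from mixtree.model import QuadratureGrid, marginal_loglik

        design = SimulationDesign(
            C_true=2, class_size_profile="equal", N=40, J=3, separation="high"
        )
        data = generate_dataset(design, seed=2)
        pseudo = decompose_to_pseudo_items(data.responses)
        cfg = FitConfig(quad_points=7)
        obj = _Objective(pseudo, 2, cfg)
        params = _heuristic_params(pseudo, 2, 0.2)
        f, _ = obj.value_and_grad(obj.packer.pack(params))
        want = marginal_loglik(
            params, pseudo, QuadratureGrid(7, 0.2)
        ).sum()
        assert -f * pseudo.n_persons == pytest.approx(want, rel=1e-10)


class TestFitStep1:
    def test_deterministic_given_seed(self):
        design = SimulationDesign(
            C_true=2, class_size_profile="equal", N=300, J=5, separation="high"
        )
        data = generate_dataset(design, seed=4)
        cfg = FitConfig(quad_points=5, n_starts=2, seed=42)
        fit_a = fit_step1(data.responses, 2, cfg)
        fit_b = fit_step1(data.responses, 2, cfg)
        assert fit_a.loglik == fit_b.loglik
        np.testing.assert_array_equal(
            fit_a.params.alpha_trait, fit_b.params.alpha_trait
        )
        np.testing.assert_array_equal(fit_a.params.omega, fit_b.params.omega)

    def test_single_class_recovery(self):
        """Correctly specified single-class fit recovers the generator."""
        design = SimulationDesign(
            C_true=1, class_size_profile="balanced", N=2000, J=20,
            separation="medium",
        )
        data = generate_dataset(design, seed=9)
        fit = fit_step1(
            data.responses, 1, FitConfig(quad_points=11, n_starts=1, seed=0)
        )
        rec = evaluate_recovery(data, fit)
        bias = rec.params.set_index("family")["bias"]
        corr = np.corrcoef(
            fit.params.alpha_trait, data.true_params.alpha_trait
        )[0, 1]
        # truth loadings are U(0.5, 1.25) (SD 0.217) and the per-loading
        # RMSE at N=2000 is ~0.075, bounding the attainable correlation
        # near 0.945; 0.90 leaves room for seed-to-seed variation
        assert corr >= 0.90
        for family in ("alpha_trait", "beta1", "beta2", "beta3"):
            assert abs(bias[family]) < 0.05

    def test_warns_on_small_samples(self):
        rng = np.random.default_rng(0)
        resp = rng.integers(1, 5, size=(50, 4)).astype(float)
        with pytest.warns(UserWarning, match="small"):
            fit_step1(resp, 1, FitConfig(quad_points=3, n_starts=1, seed=0))

    def test_nested_loglik_ordering(self, two_class_study):
        """More classes can never fit worse at the optimum."""
        for rep in two_class_study.logliks:
            assert rep[2] > rep[1]
            assert rep[3] >= rep[2] - 1e-6

    def test_canonical_label_order(self, two_class_study):
        # classes reported satisficing-like (largest ERS loading) first
        assert all(two_class_study.alpha_ers_order_ok)


# ---------------------------------------------------------------------------
# EAP scores and posteriors
# ---------------------------------------------------------------------------


def _zero_loading_fit(J=5, N=4):
    params = MixTreeParameters(
        alpha_trait=np.full(J, 1e-10),
        beta1=np.zeros(J),
        omega=np.zeros((J, 1)),
        alpha_ers=np.full(1, 1e-10),
        beta2=np.zeros((J, 1)),
        beta3=np.zeros((J, 1)),
        pi=np.ones(1),
    )
    from mixtree.estimation import FitResult

    return FitResult(
        params=params, loglik=0.0, n_starts=1, converged=True,
        start_logliks=[0.0], config=FitConfig(quad_points=15), n_persons=N,
    )


class TestEapScores:
    def test_flat_likelihood_returns_prior(self):
        fit = _zero_loading_fit()
        rng = np.random.default_rng(1)
        resp = rng.integers(1, 5, size=(4, 5)).astype(float)
        scores = eap_scores(fit, resp)
        np.testing.assert_allclose(scores.theta, 0.0, atol=1e-8)
        np.testing.assert_allclose(scores.eta, 0.0, atol=1e-8)
        np.testing.assert_allclose(scores.se_theta, 1.0, atol=1e-6)
        np.testing.assert_allclose(scores.se_eta, 1.0, atol=1e-6)

    def test_extreme_responder_scores_higher_ers(self):
        J = 5
        params = MixTreeParameters(
            alpha_trait=np.ones(J),
            beta1=np.zeros(J),
            omega=np.full((J, 1), 0.5),
            alpha_ers=np.full(1, 0.8),
            beta2=np.zeros((J, 1)),
            beta3=np.zeros((J, 1)),
            pi=np.ones(1),
        )
        from mixtree.estimation import FitResult

        fit = FitResult(
            params=params, loglik=0.0, n_starts=1, converged=True,
            start_logliks=[0.0], config=FitConfig(quad_points=15), n_persons=2,
        )
        resp = np.array([[4.0] * J, [3.0] * J])
        scores = eap_scores(fit, resp)
        assert scores.eta[0] > scores.eta[1]

    def test_average_posterior_variance_below_prior(self, small_two_class_data):
        """Law of total variance: E[Var(latent | Y)] <= prior variance 1.

        Individual respondents can exceed 1 when the class-mixture posterior
        is bimodal, but the average posterior variance cannot.
        """
        fit = fit_step1(
            small_two_class_data.responses, 2,
            FitConfig(quad_points=7, n_starts=1, seed=0),
        )
        scores = eap_scores(fit, small_two_class_data.responses)
        assert np.mean(scores.se_theta**2) <= 1.0 + 1e-6
        assert np.mean(scores.se_eta**2) <= 1.0 + 1e-6


class TestPosteriorClassProbs:
    def test_bayes_rule_hand_example(self):
        """Priors (0.6, 0.4) with likelihood ratio 1:3 give (1/3, 2/3)."""
        J = 1
        # zero loadings; class likelihoods differ only through beta3
        params = MixTreeParameters(
            alpha_trait=np.full(J, 1e-10),
            beta1=np.zeros(J),
            omega=np.zeros((J, 2)),
            alpha_ers=np.full(2, 1e-10),
            beta2=np.zeros((J, 2)),
            beta3=np.array([[np.log(0.2 / 0.8), np.log(0.6 / 0.4)]]),
            pi=np.array([0.6, 0.4]),
        )
        from mixtree.estimation import FitResult

        fit = FitResult(
            params=params, loglik=0.0, n_starts=1, converged=True,
            start_logliks=[0.0], config=FitConfig(quad_points=9), n_persons=1,
        )
        post = posterior_class_probs(fit, np.array([[4.0]]))
        # P(cat4 | c) = 0.5 * expit(beta3_c) -> likelihoods 0.1 vs 0.3
        np.testing.assert_allclose(
            post.class_post[0], [1 / 3, 2 / 3], atol=1e-10
        )

    def test_identical_classes_return_prior(self):
        params = MixTreeParameters(
            alpha_trait=np.ones(2),
            beta1=np.zeros(2),
            omega=np.full((2, 2), 0.5),
            alpha_ers=np.full(2, 0.5),
            beta2=np.zeros((2, 2)),
            beta3=np.zeros((2, 2)),
            pi=np.array([0.7, 0.3]),
        )
        from mixtree.estimation import FitResult

        fit = FitResult(
            params=params, loglik=0.0, n_starts=1, converged=True,
            start_logliks=[0.0], config=FitConfig(quad_points=9), n_persons=3,
        )
        resp = np.array([[1.0, 4.0], [2.0, 2.0], [4.0, 4.0]])
        post = posterior_class_probs(fit, resp)
        np.testing.assert_allclose(
            post.class_post, np.tile([0.7, 0.3], (3, 1)), atol=1e-12
        )

    def test_single_class_posterior_is_one(self):
        fit = _zero_loading_fit()
        post = posterior_class_probs(fit, np.array([[1.0, 2.0, 3.0, 4.0, 1.0]]))
        np.testing.assert_allclose(post.class_post, 1.0)


class TestModalAssign:
    def test_examples(self):
        post = np.array([[0.75, 0.25], [0.5, 0.5], [1.0, 0.0], [0.0, 1.0]])
        np.testing.assert_array_equal(modal_assign(post), [0, 0, 0, 1])


class TestClassificationError:
    def test_degenerate_posteriors_give_identity(self):
        post = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        err = classification_error(post, modal_assign(post))
        np.testing.assert_allclose(err.D, np.eye(2), atol=1e-12)
        assert err.total_error == pytest.approx(0.0, abs=1e-12)

    def test_hand_example(self):
        post = np.array([[0.75, 0.25], [0.25, 0.75]])
        err = classification_error(
            post, modal_assign(post), pi=np.array([0.5, 0.5])
        )
        np.testing.assert_allclose(
            err.D, [[0.75, 0.25], [0.25, 0.75]], atol=1e-12
        )
        assert err.total_error == pytest.approx(0.25, abs=1e-12)

    def test_invariant_to_respondent_order(self):
        rng = np.random.default_rng(0)
        post = rng.dirichlet(np.ones(3), size=40)
        w = modal_assign(post)
        err1 = classification_error(post, w)
        perm = rng.permutation(40)
        err2 = classification_error(post[perm], w[perm])
        np.testing.assert_allclose(err1.D, err2.D, atol=1e-12)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        post = rng.dirichlet(np.ones(3), size=100)
        err = classification_error(post, modal_assign(post))
        np.testing.assert_allclose(err.D.sum(axis=1), 1.0, atol=1e-10)

    def test_empty_class_rejected(self):
        post = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="class 2"):
            classification_error(post, modal_assign(post))


# ---------------------------------------------------------------------------
# Step 3
# ---------------------------------------------------------------------------


class TestFitStep3:
    def _simulate(self, N, gamma0, gamma, seed, D=None):
        rng = np.random.default_rng(seed)
        Z = rng.standard_normal((N, gamma.shape[0]))
        from mixtree.simulation import sample_memberships

        true, _ = sample_memberships(Z, gamma0, gamma, rng)
        if D is None:
            return Z, true
        # pass the true classes through a fixed misclassification channel
        u = rng.random(N)
        w = (D[true].cumsum(axis=1) < u[:, None]).sum(axis=1)
        return Z, w

    def test_identity_error_matrix_equals_multinomial_logit(self):
        """With D = I the corrected model is an ordinary multinomial logit."""
        import statsmodels.api as sm

        gamma0 = np.array([0.0, -0.4])
        gamma = np.array([[0.0, 0.8], [0.0, -0.5]])
        Z, w = self._simulate(800, gamma0, gamma, seed=3)
        model = fit_step3(w, np.eye(2), Z)
        sm_fit = sm.MNLogit(w, sm.add_constant(Z)).fit(disp=0)
        want = np.asarray(sm_fit.params).ravel()
        got = np.concatenate([[model.gamma0[1]], model.gamma[:, 1]])
        np.testing.assert_allclose(got, want, atol=1e-4)
        want_se = np.asarray(sm_fit.bse).ravel()
        got_se = np.concatenate([[model.se_gamma0[1]], model.se_gamma[:, 1]])
        np.testing.assert_allclose(got_se, want_se, atol=1e-3)

    def test_null_effects_recovered_near_zero(self):
        gamma0 = np.array([0.0, 0.2])
        gamma = np.zeros((3, 2))
        Z, w = self._simulate(4000, gamma0, gamma, seed=7)
        model = fit_step3(w, np.eye(2), Z)
        assert np.all(np.abs(model.gamma[:, 1]) < 0.1)

    def test_sign_pattern_recovery_with_misclassification(self):
        """Strong/weak/null effect signs survive a noisy assignment channel."""
        gamma0 = np.array([0.0, -0.37])
        gamma = np.array([[0.0, -1.0], [0.0, 0.5], [0.0, 0.0]])
        D = np.array([[0.9, 0.1], [0.1, 0.9]])
        ok = 0
        reps = 50
        for rep in range(reps):
            Z, w = self._simulate(3000, gamma0, gamma, seed=100 + rep, D=D)
            model = fit_step3(w, D, Z)
            if model.gamma[0, 1] < 0 and model.gamma[1, 1] > 0:
                ok += 1
        assert ok / reps >= 0.95

    def test_singular_covariates_rejected(self):
        Z = np.ones((100, 2))
        with pytest.raises(ValueError, match="singular"):
            fit_step3(np.zeros(100, dtype=int), np.eye(2), Z)


class TestPredictClassProbs:
    def _model(self, gamma0, gamma):
        from mixtree.estimation import CovariateModel

        return CovariateModel(
            gamma0=gamma0, gamma=gamma,
            se_gamma0=np.zeros_like(gamma0), se_gamma=np.zeros_like(gamma),
            loglik=0.0, converged=True,
        )

    def test_zero_coefficients_give_uniform(self):
        m = self._model(np.zeros(3), np.zeros((2, 3)))
        np.testing.assert_allclose(
            predict_class_probs(m, np.array([1.0, -2.0])), 1 / 3, atol=1e-12
        )

    def test_reference_three_class_configuration_at_origin(self):
        gamma0 = np.array([0.0, -0.37, -0.37])
        gamma = np.array([[0.0, -1.0, 1.0], [0.0, 0.5, -0.5], [0.0, 0.0, 0.0]])
        m = self._model(gamma0, gamma)
        got = predict_class_probs(m, np.zeros(3))
        e = np.exp(gamma0)
        np.testing.assert_allclose(got, e / e.sum(), atol=1e-12)
        np.testing.assert_allclose(got, [0.4199, 0.2900, 0.2900], atol=1e-4)


# ---------------------------------------------------------------------------
# Label alignment
# ---------------------------------------------------------------------------


class TestAlignLabels:
    def _params(self, seed=0, C=3, J=4):
        rng = np.random.default_rng(seed)
        return MixTreeParameters(
            alpha_trait=rng.uniform(0.5, 1.25, J),
            beta1=rng.normal(size=J),
            omega=rng.uniform(0.1, 0.9, (J, C)),
            alpha_ers=rng.uniform(0.2, 1.2, C),
            beta2=rng.normal(size=(J, C)),
            beta3=rng.normal(size=(J, C)),
            pi=np.full(C, 1 / C),
        )

    def test_identity_for_matching_candidate(self):
        ref = self._params()
        aligned, perm = align_labels(ref, ref)
        np.testing.assert_array_equal(perm, [0, 1, 2])

    def test_recovers_explicit_swap(self):
        ref = self._params()
        swapped = ref.permute_classes([2, 0, 1])
        aligned, perm = align_labels(ref, swapped)
        np.testing.assert_allclose(aligned.omega, ref.omega, atol=1e-14)
        np.testing.assert_allclose(aligned.alpha_ers, ref.alpha_ers, atol=1e-14)

    def test_recovers_swap_under_noise(self):
        rng = np.random.default_rng(5)
        ref = self._params(seed=2)
        noisy = ref.permute_classes([1, 2, 0])
        noisy = MixTreeParameters(
            alpha_trait=noisy.alpha_trait,
            beta1=noisy.beta1,
            omega=noisy.omega + rng.normal(0, 0.02, noisy.omega.shape),
            alpha_ers=noisy.alpha_ers + rng.normal(0, 0.02, 3),
            beta2=noisy.beta2 + rng.normal(0, 0.02, noisy.beta2.shape),
            beta3=noisy.beta3 + rng.normal(0, 0.02, noisy.beta3.shape),
            pi=noisy.pi,
        )
        aligned, perm = align_labels(ref, noisy)
        # exhaustive-search oracle over all 6 permutations
        import itertools

        def cost(p):
            cand = noisy.permute_classes(p)
            return sum(
                np.sum((getattr(ref, f) - getattr(cand, f)) ** 2)
                for f in ("omega", "alpha_ers", "beta2", "beta3")
            )

        best = min(itertools.permutations(range(3)), key=cost)
        np.testing.assert_array_equal(perm, best)
        np.testing.assert_allclose(aligned.omega, ref.omega, atol=0.1)
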