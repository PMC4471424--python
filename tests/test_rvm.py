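"""Sparse Bayesian classifier: design, MAP step, evidence updates, prediction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, optimize

from warfdose.errors import DegenerateModelError, ValidationError
from warfdose.rvm import (
    BasisSpec,
    build_design,
    fit_rvm,
    irls_map,
    load_rvm,
    predict_class,
    predict_prob,
    save_rvm,
    sigmoid,
    update_alpha,
)


class TestSigmoid:
    def test_zero_maps_to_half(self):
        assert sigmoid(0.0) == 0.5

    def test_extremes_are_clipped(self):
        assert sigmoid(1e6) == 1 - 1e-12
        assert sigmoid(-1e6) == 1e-12

    @given(st.floats(-50, 50))
    @settings(deadline=None)
    def test_complement_identity(self, y):
        assert sigmoid(y) + sigmoid(-y) == pytest.approx(1.0, abs=1e-9)


class TestBuildDesign:
    def test_linear_design_has_bias_column(self):
        X = np.arange(6.0).reshape(3, 2)
        Phi = build_design(X, BasisSpec(kind="linear"))
        assert Phi.shape == (3, 3)
        assert np.all(Phi[:, 0] == 1.0)

    def test_rbf_self_kernel_is_one(self):
        X = np.random.default_rng(0).normal(size=(5, 2))
        Phi = build_design(X, BasisSpec(kind="rbf", rbf_width=1.0))
        assert np.allclose(np.diag(Phi[:, 1:]), 1.0)

    def test_rbf_wide_width_limit(self):
        X = np.random.default_rng(0).normal(size=(4, 2))
        Phi = build_design(X, BasisSpec(kind="rbf", rbf_width=1e8))
        assert np.allclose(Phi[:, 1:], 1.0, atol=1e-10)

    def test_zero_variance_feature_excluded(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        basis = BasisSpec(kind="linear")
        Phi = build_design(X, basis)
        assert Phi.shape == (5, 2)  # bias + one informative feature

    def test_standardization_frozen_at_training(self):
        rng = np.random.default_rng(1)
        X = rng.normal(2.0, 3.0, size=(20, 2))
        basis = BasisSpec(kind="linear")
        build_design(X, basis)
        row = build_design(X[:1] * 10, basis)
        expected = (X[0] * 10 - basis.feature_means) / basis.feature_sds
        assert np.allclose(row[0, 1:], expected)


class TestIrlsMap:
    def test_huge_alpha_pins_weight_to_zero(self):
        rng = np.random.default_rng(0)
        Phi = rng.normal(size=(30, 1))
        z = (rng.random(30) < 0.5).astype(float)
        w, _ = irls_map(Phi, z, np.array([1e10]))
        assert abs(w[0]) < 1e-6

    def test_balanced_labels_bias_only_gives_zero(self):
        Phi = np.ones((10, 1))
        z = np.array([0.0, 1.0] * 5)
        w, _ = irls_map(Phi, z, np.array([1.0]))
        assert abs(w[0]) < 1e-8

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_direct_optimizer(self, seed):
        """MAP weights agree with BFGS on the same penalized log-likelihood."""
        rng = np.random.default_rng(seed)
        n, m = 15, 3
        Phi = rng.normal(size=(n, m))
        z = rng.integers(0, 2, n).astype(float)
        alpha = np.exp(rng.normal(0, 0.5, m))
        w, sigma = irls_map(Phi, z, alpha)

        def neg(wv):
            p = np.clip(1 / (1 + np.exp(-Phi @ wv)), 1e-12, 1 - 1e-12)
            return -(np.sum(z * np.log(p) + (1 - z) * np.log(1 - p))
                     - 0.5 * np.sum(alpha * wv**2))

        ref = optimize.minimize(neg, np.zeros(m), method="BFGS", options={"gtol": 1e-12})
        assert np.max(np.abs(w - ref.x)) < 1e-5
        assert np.max(np.abs(sigma - sigma.T)) < 1e-8

    def test_rejects_bad_labels(self):
        with pytest.raises(ValidationError):
            irls_map(np.ones((3, 1)), np.array([0.0, 1.0, 2.0]), np.array([1.0]))


class TestUpdateAlpha:
    def test_direct_substitution(self):
        # gamma = 1, w = 0.5 -> alpha' = 4
        new = update_alpha(np.array([0.5]), np.array([[0.0]]), np.array([2.0]))
        assert new[0] == pytest.approx(4.0)

    def test_prior_untouched_by_data_forces_pruning(self):
        # Sigma_ii = 1/alpha_i -> gamma = 0 -> prune
        alpha = np.array([2.0])
        new = update_alpha(np.array([0.3]), np.array([[0.5]]), alpha, prune_threshold=1e9)
        assert new[0] >= 1e9

    def test_zero_weight_forces_pruning(self):
        new = update_alpha(np.array([0.0]), np.array([[0.1]]), np.array([1.0]))
        assert new[0] >= 1e9

    def test_one_weight_iteration_converges_to_update_fixed_point(self):
        """Alternating MAP/alpha updates land on the update map's own fixed
        point (located independently by grid scan), which sits near the 1-D
        evidence maximum."""
        rng = np.random.default_rng(4)
        Phi = rng.normal(size=(40, 1))
        eta = 1.5 * Phi[:, 0]
        z = (rng.random(40) < 1 / (1 + np.exp(-eta))).astype(float)

        alpha = np.array([1.0])
        for _ in range(200):
            w, sigma = irls_map(Phi, z, alpha)
            alpha = update_alpha(w, sigma, alpha)

        # brute force: where does the update map cross the identity?
        grid = np.logspace(-3, 3, 2000)
        gaps = []
        for a in grid:
            wg, sg = irls_map(Phi, z, np.array([a]))
            na = update_alpha(wg, sg, np.array([a]))
            gaps.append(abs(np.log(na[0]) - np.log(a)))
        crossing = grid[int(np.argmin(gaps))]
        assert np.log(alpha[0]) == pytest.approx(np.log(crossing), abs=0.02)

        # and that fixed point lies near the brute-force evidence maximum
        from warfdose.rvm import _log_evidence

        evs = []
        sub = np.logspace(-3, 3, 200)
        for a in sub:
            wg, sg = irls_map(Phi, z, np.array([a]))
            evs.append(_log_evidence(Phi, z, np.array([a]), wg, sg, 1e-8))
        best = sub[int(np.argmax(evs))]
        assert np.log(alpha[0]) == pytest.approx(np.log(best), abs=0.5)


class TestFitRVM:
    def test_separable_toy_perfect_accuracy_and_sparse(self, blob_toy):
        X, z = blob_toy
        m = fit_rvm(X, z)
        assert np.mean(predict_class(m, X) == z) == 1.0
        assert len(m.relevance_indices) < len(z)
        assert len(m.relevance_indices) <= 0.2 * len(z)

    def test_rbf_prunes_on_noisy_toy(self):
        rng = np.random.default_rng(3)
        n = 100
        X = np.vstack([rng.normal([-1, -1], 1.0, (n // 2, 2)),
                       rng.normal([1, 1], 1.0, (n // 2, 2))])
        z = np.array([0] * (n // 2) + [1] * (n // 2))
        m = fit_rvm(X, z, BasisSpec(kind="rbf", rbf_width=1.0))
        assert len(m.relevance_indices) <= 10
        assert np.mean(predict_class(m, X) == z) >= 0.9

    def test_null_labels_predict_prevalence(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 3))
        z = rng.integers(0, 2, 60)
        m = fit_rvm(X, z)
        p = predict_prob(m, rng.normal(size=(200, 3)))
        assert np.max(np.abs(p - z.mean())) < 0.1

    def test_single_class_labels_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(DegenerateModelError):
            fit_rvm(X, np.zeros(10))

    def test_evidence_trace_nondecreasing_on_toy(self, blob_toy):
        X, z = blob_toy
        m = fit_rvm(X, z)
        assert len(m.trace) >= 1
        assert np.all(np.diff(m.trace) > -1e-6)

    def test_permutation_equivariance(self, blob_toy):
        X, z = blob_toy
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(z))
        grid = rng.normal(0, 2, size=(30, 2))
        p1 = predict_prob(fit_rvm(X, z, BasisSpec(kind="rbf", rbf_width=1.0)), grid)
        p2 = predict_prob(fit_rvm(X[perm], z[perm], BasisSpec(kind="rbf", rbf_width=1.0)), grid)
        assert np.allclose(p1, p2, atol=1e-6)

    def test_label_flip_flips_predictions(self, blob_toy):
        X, z = blob_toy
        grid = np.random.default_rng(6).normal(0, 2, size=(25, 2))
        c1 = predict_class(fit_rvm(X, z), grid)
        c2 = predict_class(fit_rvm(X, 1 - z), grid)
        assert np.all(c1 == 1 - c2)


class TestPredict:
    @pytest.fixture
    def toy_model(self, blob_toy):
        X, z = blob_toy
        return fit_rvm(X, z)

    def test_moderated_equals_plugin_at_zero_variance(self, toy_model):
        toy_model.sigma_post = np.zeros_like(toy_model.sigma_post)
        x = np.array([1.0, 1.0])
        assert predict_prob(toy_model, x, "moderated") == pytest.approx(
            predict_prob(toy_model, x, "plugin")
        )

    def test_zero_mean_gives_half_regardless_of_variance(self, toy_model):
        toy_model.w_map = np.zeros_like(toy_model.w_map)
        x = np.array([0.3, -0.4])
        assert predict_prob(toy_model, x, "moderated") == pytest.approx(0.5)

    @pytest.mark.parametrize("mu,s2", [(0.8, 2.3), (-1.5, 0.5), (2.0, 4.0), (0.1, 9.0)])
    def test_moderated_matches_quadrature(self, mu, s2):
        """Probit approximation tracks the exact 1-D Gaussian marginal."""
        exact = integrate.quad(
            lambda y: (1 / (1 + np.exp(-y)))
            * np.exp(-((y - mu) ** 2) / (2 * s2))
            / np.sqrt(2 * np.pi * s2),
            -50, 50,
        )[0]
        approx = sigmoid(mu / np.sqrt(1 + np.pi * s2 / 8))
        assert approx == pytest.approx(exact, abs=0.02)

    def test_decision_boundary_inclusive(self, toy_model):
        toy_model.w_map = np.zeros_like(toy_model.w_map)
        x = np.array([0.0, 0.0])
        assert predict_class(toy_model, x, cutoff=0.5) == 1  # prob 0.5 >= cutoff
        assert predict_class(toy_model, x, cutoff=0.51) == 0

    def test_serialization_round_trip(self, toy_model, tmp_path):
        path = tmp_path / "rvm.json"
        save_rvm(toy_model, path)
        back = load_rvm(path)
        grid = np.random.default_rng(8).normal(0, 2, size=(20, 2))
        assert np.array_equal(predict_prob(toy_model, grid), predict_prob(back, grid))
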