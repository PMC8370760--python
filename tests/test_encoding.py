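"""Feature selection, non-negative lasso, lambda tuning and CV predictions."""

import itertools

import numpy as np
import pytest

from mvreact.encoding import (EncodingModel, default_lambda_grid,
                              fit_encoding_models, fit_nnlasso,
                              fit_vertex_model, make_fold_plan,
                              nnlasso_objective, predict_patterns,
                              select_features, select_lambda)


def qp_oracle(F, v, lam):
    """Exact non-negative lasso optimum by enumerating active sets.

    For each support S, solve the equality-constrained stationarity system
    (F_S'F_S) h_S = F_S'v - lam; keep non-negative solutions; the convex
    optimum's active set is among them, so the minimum objective over
    feasible candidates (including the empty support) is the optimum.
    """
    p = F.shape[1]
    best = nnlasso_objective(F, v, np.zeros(p), lam)
    for r in range(1, p + 1):
        for S in itertools.combinations(range(p), r):
            Fs = F[:, S]
            try:
                hs = np.linalg.solve(Fs.T @ Fs, Fs.T @ v - lam)
            except np.linalg.LinAlgError:
                continue
            if np.all(hs >= -1e-12):
                h = np.zeros(p)
                h[list(S)] = np.maximum(hs, 0.0)
                best = min(best, nnlasso_objective(F, v, h, lam))
    return best


class TestSelectFeatures:
    def test_copy_of_target_ranked_first(self, rng):
        v = rng.standard_normal(30)
        F = rng.standard_normal((30, 6))
        F[:, 4] = v
        sel = select_features(F, v)
        assert sel[0] == 4

    def test_all_negative_correlations_give_empty_selection(self, rng):
        v = np.linspace(0, 1, 20)
        F = -v[:, None] + 0.01 * rng.standard_normal((20, 4))
        assert select_features(F, v).size == 0

    def test_matches_sort_by_correlation_oracle(self, rng):
        F = rng.standard_normal((25, 5))
        v = rng.standard_normal(25)
        r = np.array([np.corrcoef(F[:, j], v)[0, 1] for j in range(5)])
        expected = [j for j in np.argsort(-r) if r[j] > 0]
        assert select_features(F, v).tolist() == expected

    def test_zero_variance_columns_excluded_and_k_respected(self, rng):
        F = rng.standard_normal((20, 8))
        F[:, 2] = 1.0
        v = F[:, 0] + 0.1 * rng.standard_normal(20)
        sel = select_features(F, v, k=3)
        assert 2 not in sel and len(sel) <= 3


class TestNnlasso:
    def test_huge_penalty_zeroes_weights(self, rng):
        F = rng.standard_normal((20, 4))
        v = rng.standard_normal(20)
        lam = np.abs(F.T @ v).max() * 1.1
        assert np.allclose(fit_nnlasso(F, v, lam), 0.0)

    def test_orthonormal_unpenalized_recovery(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((30, 4)))
        h_true = np.array([0.5, 0.0, 2.0, 1.0])
        v = q @ h_true
        h = fit_nnlasso(q, v, 0.0)
        assert np.allclose(h, h_true, atol=1e-6)

    def test_matches_qp_oracle_on_random_instances(self, rng):
        for _ in range(12):
            F = rng.standard_normal((6, 4))
            v = rng.standard_normal(6)
            lam = float(rng.uniform(0.01, 1.0))
            h = fit_nnlasso(F, v, lam)
            assert np.all(h >= 0)
            obj = nnlasso_objective(F, v, h, lam)
            assert abs(obj - qp_oracle(F, v, lam)) < 1e-6

    def test_negative_penalty_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_nnlasso(rng.standard_normal((5, 2)), rng.standard_normal(5),
                        -1.0)


class TestSelectLambda:
    def test_grid_is_five_log_spaced_points(self):
        g = default_lambda_grid()
        assert len(g) == 5
        assert g[0] == pytest.approx(1e-4) and g[-1] == pytest.approx(1.0)
        ratios = g[1:] / g[:-1]
        assert np.allclose(ratios, ratios[0])

    def test_single_point_grid_returned(self, rng):
        F = rng.standard_normal((20, 3))
        v = rng.standard_normal(20)
        lam, _ = select_lambda(F[:15], v[:15], F[15:], v[15:],
                               grid=np.array([0.3]))
        assert lam == 0.3

    def test_achieves_grid_minimal_heldout_sse(self, rng):
        # sparse non-negative truth; oracle evaluates every grid point
        F = np.abs(rng.standard_normal((60, 10)))
        h_true = np.zeros(10)
        h_true[[1, 4]] = [1.0, 0.5]
        v = F @ h_true + 0.1 * rng.standard_normal(60)
        tr, va = slice(0, 40), slice(40, 60)
        grid = default_lambda_grid()
        lam, sse = select_lambda(F[tr], v[tr], F[va], v[va], grid=grid)
        oracle_sse = []
        for g in grid:
            h = fit_nnlasso(F[tr], v[tr], g)
            resid = v[va] - F[va] @ h
            oracle_sse.append(resid @ resid)
        assert lam == grid[int(np.argmin(oracle_sse))]
        # warm-started vs cold-started descent agree to convergence tolerance
        assert np.allclose(sse, oracle_sse, rtol=1e-4, atol=1e-6)
        assert sse[list(grid).index(lam)] <= sse.min() + 1e-12

    def test_ties_prefer_smaller_lambda(self, rng):
        # with no validation signal all lambdas give identical SSE=const
        F = rng.standard_normal((20, 2))
        v = rng.standard_normal(20)
        lam, sse = select_lambda(F[:15], v[:15], np.zeros((5, 2)),
                                 np.zeros(5), grid=np.array([0.5, 0.1, 0.9]))
        # ties on SSE resolve to the smallest grid value
        if np.allclose(sse, sse[0]):
            assert lam == 0.1


class TestVertexModelsAndPredictions:
    def test_weight_nonnegativity_enforced(self):
        with pytest.raises(ValueError):
            EncodingModel(0, 1, 0, np.array([0, 1]), np.array([0.5, -0.1]),
                          0.1)

    def test_single_feature_prediction_proportional(self, rng):
        # one vertex driven by feature 0 exactly: prediction tracks it
        F = np.abs(rng.standard_normal((40, 5)))
        v = 2.0 * F[:, 0]
        val = np.zeros(40, bool)
        val[30:] = True
        m = fit_vertex_model(F, v, val, standardize=False,
                             grid=np.array([1e-6]))
        pred = m.predict(F)
        assert np.corrcoef(pred, F[:, 0])[0, 1] > 0.999

    def test_empty_selection_predicts_constant(self, rng):
        F = -np.abs(rng.standard_normal((30, 4)))
        v = F[:, 0] * -1.0  # negatively correlated with every column
        val = np.zeros(30, bool)
        val[20:] = True
        m = fit_vertex_model(F, v, val)
        assert m.selected_features.size == 0
        assert np.allclose(m.predict(F), v[~val].mean())

    def _tiny_problem(self, rng, n_images=9, p=6, n_vertices=2, reps=2):
        images = [f"im{i}" for i in range(n_images)]
        feats = {1: np.abs(rng.standard_normal((n_images, p)))}
        trial_images = images * reps
        rows = np.array([images.index(i) for i in trial_images])
        W = np.abs(rng.standard_normal((n_vertices, p)))
        betas = feats[1][rows] @ W.T + 0.05 * rng.standard_normal(
            (len(rows), n_vertices))
        plan = make_fold_plan(images, n_folds=3, rng=rng)
        return images, feats, trial_images, betas, plan

    def test_fold_bookkeeping_no_leakage(self, rng):
        images, feats, trial_images, betas, plan = self._tiny_problem(rng)
        for img in images:
            fold = plan.fold_for_image(img)
            assert img in plan.held_out(fold)
            assert img not in plan.training_images(fold)
            others = [f for f in range(plan.n_folds) if f != fold]
            for f in others:
                assert img not in plan.held_out(f)

    def test_predictions_use_heldout_fold_models(self, rng):
        images, feats, trial_images, betas, plan = self._tiny_problem(rng)
        models = fit_encoding_models(feats, images, betas, trial_images, plan,
                                     k=6, grid=np.array([1e-4]))
        preds = predict_patterns(models, feats, images, plan)
        assert preds[1].shape == (len(images), betas.shape[1])
        # recompute each image's prediction directly from its held-out fold
        for i, img in enumerate(images):
            fold = plan.fold_for_image(img)
            for vx, m in enumerate(models[1][fold]):
                assert preds[1][i, vx] == pytest.approx(
                    m.predict(feats[1][i][None, :])[0])

    def test_every_fitted_weight_vector_nonnegative(self, rng):
        images, feats, trial_images, betas, plan = self._tiny_problem(rng)
        models = fit_encoding_models(feats, images, betas, trial_images, plan,
                                     k=6)
        for per_fold in models.values():
            for fold_models in per_fold.values():
                for m in fold_models:
                    assert np.all(m.weights >= 0)
                    assert m.lambda_ in default_lambda_grid()


def test_weight_recovery_cosine(rng):
    """Sparse non-negative truth recovered at moderate noise (n=240)."""
    n, p = 240, 120
    F = np.abs(rng.standard_normal((n, p)))
    h_true = np.zeros(p)
    support = rng.choice(p, size=10, replace=False)
    h_true[support] = rng.exponential(1.0, size=10)
    signal = F @ h_true
    v = signal + 0.1 * signal.std() * rng.standard_normal(n)
    val = np.zeros(n, bool)
    val[rng.choice(n, size=60, replace=False)] = True
    m = fit_vertex_model(F, v, val, k=100, standardize=False)
    h_hat = np.zeros(p)
    h_hat[m.selected_features] = m.weights
    cosine = h_hat @ h_true / (np.linalg.norm(h_hat) * np.linalg.norm(h_true))
    assert cosine >= 0.8
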