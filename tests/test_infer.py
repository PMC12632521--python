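import numpy as np
import pytest

from serialcoal import (
    DemographicModel,
    EdgeSet,
    EpochParams,
    MeanMatrix,
    cross_validate_lambda,
    equilibrium_mean,
    full_edge_set,
    grid_edge_set,
    impute_B_equilibrium,
    infer_L_vertical,
    infer_gamma_diagonal,
    mean_at,
    mean_diagonal,
    mean_vertical,
    refine_B,
    sequential_migration_inference,
)
from serialcoal.simulate import random_epoch, simulate_mean_matrix


@pytest.fixture
def two_deme_edges():
    return EdgeSet(d=2, edges=[(0, 1), (1, 0)])


class TestInferLVertical:
    def test_noiseless_recovery(self, two_deme_edges):
        L_true = np.array([[0.5, -0.5], [-0.2, 0.2]])
        Bo = MeanMatrix(1.0, 1.0, [[4.0, 5.0], [5.0, 4.0]])
        By = mean_vertical(Bo, L_true, 1.0)
        fit = infer_L_vertical(Bo, By, 1.0, two_deme_edges, lam=0.0)
        np.testing.assert_allclose(fit.weights, [0.5, 0.2], atol=1e-3)

    def test_zero_migration_truth(self, two_deme_edges):
        Bo = MeanMatrix(1.0, 1.0, [[4.0, 5.0], [5.0, 4.0]])
        By = MeanMatrix(0.0, 1.0, Bo.B + 1.0)
        fit = infer_L_vertical(Bo, By, 1.0, two_deme_edges)
        assert fit.weights.max() < 1e-4

    def test_nonpositive_observation_rejected(self, two_deme_edges):
        Bo = MeanMatrix(1.0, 1.0, [[4.0, 5.0], [5.0, 4.0]])
        By = MeanMatrix(0.0, 1.0, [[5.0, -1.0], [6.0, 5.0]])
        with pytest.raises(ValueError, match="positive"):
            infer_L_vertical(Bo, By, 1.0, two_deme_edges)

    def test_decoupled_from_coalescence_rates(self, two_deme_edges):
        # bit-identical output whatever gamma generated the surrounding
        # scenario: the vertical relation never sees coalescence rates
        Bo = MeanMatrix(1.0, 1.0, [[4.0, 5.0], [5.0, 4.0]])
        By = MeanMatrix(0.0, 1.0, [[5.3, 5.9], [5.8, 5.2]])
        results = []
        for gamma in ([1.0, 1.0], [0.1, 7.0]):
            EpochParams(0.0, np.inf, M=[[0, 1], [1, 0]], gamma=gamma)  # scenario context
            results.append(infer_L_vertical(Bo, By, 1.0, two_deme_edges).weights)
        np.testing.assert_array_equal(results[0], results[1])

    def test_absolute_scale_regression_slope(self, rng):
        # weights are recovered in absolute units, not up to a constant
        ep = random_epoch(5, rng)
        es = full_edge_set(5)
        Bo = MeanMatrix(1.0, 1.0, equilibrium_mean(ep))
        By = mean_vertical(Bo, ep.L, 1.0)
        fit = infer_L_vertical(Bo, By, 1.0, es)
        w_true = es.weights_from_M(ep.M)
        slope = np.polyfit(w_true, fit.weights, 1)[0]
        assert 0.9 < slope < 1.1


class TestRefineB:
    def test_true_L_reproduces_vertical_relation(self, sym2_epoch):
        Bo = MeanMatrix(1.0, 1.0, equilibrium_mean(sym2_epoch))
        expected = mean_vertical(Bo, sym2_epoch.L, 1.0)
        out = refine_B(Bo, sym2_epoch.L, 1.0)
        np.testing.assert_allclose(out.B, expected.B, atol=1e-14)

    def test_zero_L_is_pure_shift(self):
        Bo = MeanMatrix(1.0, 1.0, [[4.0, 5.0], [5.0, 4.0]])
        out = refine_B(Bo, np.zeros((2, 2)), 1.0)
        np.testing.assert_allclose(out.B, Bo.B + 1.0)

    def test_refinement_reduces_noise(self, sym2_epoch):
        # projected estimate beats the raw sample mean once L is known
        model = DemographicModel([sym2_epoch])
        truth = mean_at(model, 0.0, 1.0).B
        rmse_raw, rmse_ref = [], []
        for seed in range(5):
            B_hat, _ = simulate_mean_matrix(model, 0.0, 1.0, 2000, seed=seed)
            B_old, _ = simulate_mean_matrix(model, 1.0, 1.0, 10_000, seed=100 + seed)
            refined = refine_B(B_old, sym2_epoch.L, 1.0)
            rmse_raw.append(np.sqrt(np.mean((B_hat.B - truth) ** 2)))
            rmse_ref.append(np.sqrt(np.mean((refined.B - truth) ** 2)))
        assert np.mean(rmse_ref) < np.mean(rmse_raw)


class TestSequentialInference:
    def test_three_epoch_noiseless_recovery(self, rng):
        d = 3
        eps = [
            random_epoch(d, rng, t_start=0.0, t_end=1.0),
            random_epoch(d, rng, t_start=1.0, t_end=2.0),
            random_epoch(d, rng, t_start=2.0),
        ]
        model = DemographicModel(eps)
        data = {
            key: mean_at(model, *key)
            for key in [(2.0, 2.0), (1.0, 2.0), (0.0, 2.0)]
        }
        es = full_edge_set(d)
        res = sequential_migration_inference(data, [0.0, 1.0, 2.0], es)
        for k in (0, 1):
            w_true = es.weights_from_M(eps[k].M)
            big = w_true > 1e-6
            rel = np.abs(res.weights[k] - w_true)[big] / w_true[big]
            assert rel.max() < 1e-3
            assert res.weights[k][~big].max(initial=0.0) < 1e-3

    def test_single_slice_degenerate(self, sym2_epoch, two_deme_edges):
        B = MeanMatrix(0.0, 0.0, equilibrium_mean(sym2_epoch))
        res = sequential_migration_inference({(0.0, 0.0): B}, [0.0], two_deme_edges)
        assert res.L_hat == {} and res.refined[(0.0, 0.0)] is B

    def test_vacant_demes_error_lists_them(self, two_deme_edges):
        B = MeanMatrix(0.0, 0.0, [[4.0, np.nan], [np.nan, np.nan]])
        with pytest.raises(ValueError, match=r"vacant demes \[0, 1\]"):
            sequential_migration_inference({(0.0, 0.0): B}, [0.0], two_deme_edges)

    def test_joint_protocol_recovers_gamma(self, rng):
        d = 2
        eps = [
            random_epoch(d, rng, t_start=0.0, t_end=1.0),
            random_epoch(d, rng, t_start=1.0),
        ]
        model = DemographicModel(eps)
        data = {
            key: mean_at(model, *key)
            for key in [(1.0, 1.0), (0.0, 1.0), (0.0, 0.0)]
        }
        res = sequential_migration_inference(
            data, [0.0, 1.0], full_edge_set(d), estimate_gamma=True
        )
        np.testing.assert_allclose(res.gamma_hat[0], eps[0].gamma, rtol=1e-3)


class TestImputation:
    def test_complete_input_returned_unchanged(self, two_deme_edges):
        B = MeanMatrix(0.0, 0.0, [[4.0, 5.0], [5.0, 4.0]])
        out = impute_B_equilibrium(B, two_deme_edges)
        assert not out.imputed and out.B_full is B

    def test_missing_between_cell_recovered(self, two_deme_edges):
        # equilibrium matrices are symmetric, so one off-diagonal cell is
        # pinned by the other three under the model-based fit
        B = MeanMatrix(0.0, 0.0, [[4.0, np.nan], [5.0, 4.0]])
        out = impute_B_equilibrium(B, two_deme_edges)
        np.testing.assert_allclose(out.B_full.B[0, 1], 5.0, atol=1e-2)

    def test_fully_missing_rejected(self, two_deme_edges):
        B = MeanMatrix(0.0, 0.0, np.full((2, 2), np.nan))
        with pytest.raises(ValueError, match="fully missing"):
            impute_B_equilibrium(B, two_deme_edges)

    def test_underdetermined_fit_warns(self, two_deme_edges, caplog):
        B = MeanMatrix(0.0, 0.0, [[4.0, np.nan], [np.nan, np.nan]])
        with caplog.at_level("WARNING"):
            impute_B_equilibrium(B, two_deme_edges)
        assert "underdetermined" in caplog.text


class TestGammaDiagonal:
    def test_exact_inputs_recover_truth(self, rng):
        ep = random_epoch(2, rng, t_start=0.0, t_end=1.0)
        B_old = MeanMatrix(1.0, 1.0, equilibrium_mean(random_epoch(2, rng, t_start=1.0)))
        B_young = mean_diagonal(B_old, ep, 1.0)
        gamma, report = infer_gamma_diagonal(B_young, B_old, ep.L, 1.0)
        np.testing.assert_allclose(gamma, ep.gamma, rtol=1e-3)
        assert report["non_identifiable"] == []

    def test_equilibrium_inputs_reduce_to_equilibrium_fit(self, rng):
        # when the young slice is already at equilibrium, the diagonal term
        # vanishes and gamma solves the pure equilibrium equation
        ep = random_epoch(2, rng, t_start=0.0, t_end=50.0)
        Bstar = equilibrium_mean(ep)
        gamma, _ = infer_gamma_diagonal(
            MeanMatrix(0.0, 0.0, Bstar), MeanMatrix(50.0, 50.0, Bstar), ep.L, 50.0
        )
        np.testing.assert_allclose(gamma, ep.gamma, rtol=1e-3)

    def test_rmse_decreases_with_sample_size(self, rng):
        ep = EpochParams(0.0, 1.0, M=[[0, 0.6], [0.9, 0]], gamma=[0.8, 1.5])
        term = EpochParams(1.0, np.inf, M=[[0, 1.0], [1.0, 0]], gamma=[1.0, 1.0])
        model = DemographicModel([ep, term])
        B_old = MeanMatrix(1.0, 1.0, equilibrium_mean(term))
        errs = []
        for n in (100, 1000, 10_000):
            rmses = []
            for seed in range(3):
                B_hat, _ = simulate_mean_matrix(model, 0.0, 0.0, n, seed=seed)
                gamma, _ = infer_gamma_diagonal(B_hat, B_old, ep.L, 1.0)
                rmses.append(np.sqrt(np.mean((gamma / ep.gamma - 1.0) ** 2)))
            errs.append(np.mean(rmses))
        assert errs[2] < errs[0]


class TestCrossValidation:
    def test_single_lambda_grid_trivial(self, two_deme_edges):
        Bo = MeanMatrix(1.0, 1.0, [[4.0, 5.0], [5.0, 4.0]])
        By = mean_vertical(Bo, np.array([[0.5, -0.5], [-0.2, 0.2]]), 1.0)
        cv = cross_validate_lambda(Bo, By, 1.0, two_deme_edges, [0.0], n_folds=2)
        assert cv.best_lambda == 0.0

    def test_noiseless_data_selects_smallest_lambda(self, rng):
        ep = random_epoch(4, rng)
        es = full_edge_set(4)
        Bo = MeanMatrix(1.0, 1.0, equilibrium_mean(ep))
        By = mean_vertical(Bo, ep.L, 1.0)
        cv = cross_validate_lambda(Bo, By, 1.0, es, [0.0, 0.1, 1.0], n_folds=4, seed=1)
        assert cv.best_lambda == 0.0
        assert np.all(np.diff(cv.mean_errors) >= -1e-12)

    def test_heavy_noise_prefers_regularization(self):
        # smoothness penalty wins under noise for most replicate seeds
        rows = cols = 3
        grid_truth = np.full(
            len(grid_edge_set(rows, cols).edges), 0.5
        )  # perfectly smooth truth
        es = grid_edge_set(rows, cols)
        L = es.weights_to_L(grid_truth)
        ep = EpochParams(1.0, np.inf, M=es.weights_to_M(grid_truth), gamma=np.ones(9))
        Bo = MeanMatrix(1.0, 1.0, equilibrium_mean(ep))
        By_clean = mean_vertical(Bo, L, 1.0)
        wins = 0
        n_rep = 10
        for seed in range(n_rep):
            noise_rng = np.random.default_rng(seed)
            By = MeanMatrix(
                0.0, 1.0, By_clean.B * (1 + 0.05 * noise_rng.standard_normal((9, 9)))
            )
            cv = cross_validate_lambda(
                Bo, By, 1.0, es, [0.0, 1.0], n_folds=3, seed=seed, maxiter=200
            )
            wins += cv.best_lambda > 0
        assert wins / n_rep > 0.9

    def test_determinism_given_seed(self, two_deme_edges):
        Bo = MeanMatrix(1.0, 1.0, [[4.0, 5.0], [5.0, 4.0]])
        By = MeanMatrix(0.0, 1.0, [[5.3, 5.9], [5.8, 5.2]])
        a = cross_validate_lambda(Bo, By, 1.0, two_deme_edges, [0.0, 0.1], n_folds=2, seed=3)
        b = cross_validate_lambda(Bo, By, 1.0, two_deme_edges, [0.0, 0.1], n_folds=2, seed=3)
        np.testing.assert_array_equal(a.mean_errors, b.mean_errors)
        assert a.folds == b.folds
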