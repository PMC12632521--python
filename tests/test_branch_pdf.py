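import numpy as np
import pytest

from serialcoal import (
    DemographicModel,
    EpochParams,
    equilibrium_mean,
    horizontal_pdf_check,
    pdf_at,
    propagate_diagonal,
    propagate_vertical,
    stationary_pdf,
    transition_matrix,
)
from serialcoal.simulate import random_epoch, simulate_branch_lengths

from conftest import random_model
from _oracles import upwind_diagonal_oracle


class TestStationaryPdf:
    def test_single_deme_exponential(self, d1_epoch):
        f = stationary_pdf(d1_epoch, b_max=40, db=0.01)
        b = f.b_grid
        np.testing.assert_allclose(
            f.values[:, 0, 0], 0.5 * np.exp(-b / 2.0), atol=1e-12
        )
        np.testing.assert_allclose(f.mass(), 1.0, atol=1e-4)
        np.testing.assert_allclose(f.mean(), 2.0, atol=1e-4)

    def test_mean_equals_equilibrium_matrix(self, sym2_epoch):
        f = stationary_pdf(sym2_epoch, b_max=60, db=0.01)
        np.testing.assert_allclose(
            f.mean(), [[4.0, 5.0], [5.0, 4.0]], atol=1e-4
        )

    def test_boundary_value_is_half_gamma(self, rng):
        # f*(0) = diag(gamma) / 2: fresh coalescence spread over width-2 db
        ep = random_epoch(3, rng)
        f = stationary_pdf(ep, b_max=20, db=0.02)
        np.testing.assert_allclose(f.values[0], np.diag(ep.gamma) / 2.0, atol=1e-12)

    def test_paper_literal_form_doubles_the_mass(self, d1_epoch):
        # the uncorrected printed normalization integrates to 2, not 1
        f = stationary_pdf(d1_epoch, b_max=40, db=0.01, paper_literal=True)
        np.testing.assert_allclose(f.mass(), 2.0, atol=2e-4)


class TestPropagateVertical:
    def test_zero_duration_identity(self, d1_epoch):
        f = stationary_pdf(d1_epoch, b_max=20, db=0.01)
        g = propagate_vertical(f, d1_epoch.L, 0.0)
        np.testing.assert_array_equal(g.values, f.values)

    def test_single_deme_pure_shift(self, d1_epoch):
        f = stationary_pdf(d1_epoch, b_max=20, db=0.01)
        g = propagate_vertical(f, d1_epoch.L, 3.0)
        assert g.offset == 3.0
        np.testing.assert_array_equal(g.values, f.values)  # shape unchanged, shifted support
        np.testing.assert_allclose(g.mass(), 1.0, atol=1e-4)
        np.testing.assert_allclose(g.mean(), 5.0, atol=1e-4)

    def test_two_deme_mixture_weights(self, sym2_epoch):
        # e^{-L tau} = [[.75, .25], [.25, .75]] at tau = ln(2)/2
        tau = 0.5 * np.log(2.0)
        f = stationary_pdf(sym2_epoch, b_max=50, db=0.01)
        g = propagate_vertical(f, sym2_epoch.L, tau)
        expected = 0.75 * f.values[:, 0, :] + 0.25 * f.values[:, 1, :]
        np.testing.assert_allclose(g.values[:, 0, :], expected, atol=1e-12)

    def test_mass_preserved_exactly(self, sym2_epoch):
        # stochastic mixing + shift: per-entry mass maps exactly through
        # e^{-L tau}, and stays unit within quadrature tolerance
        f = stationary_pdf(sym2_epoch, b_max=50, db=0.01)
        g = propagate_vertical(f, sym2_epoch.L, 1.7)
        T = transition_matrix(sym2_epoch.L, 1.7)
        np.testing.assert_allclose(g.mass(), T @ f.mass(), atol=1e-12)
        np.testing.assert_allclose(g.mass(), 1.0, atol=1e-4)

    def test_epoch_boundary_crossing_rejected(self, sym2_epoch):
        ep = EpochParams(2.0, 4.0, M=sym2_epoch.M, gamma=sym2_epoch.gamma)
        f = stationary_pdf(sym2_epoch, b_max=20, db=0.01, t=4.0)
        with pytest.raises(ValueError, match="chain"):
            propagate_vertical(f, ep, 3.0)


class TestPropagateDiagonal:
    def test_zero_duration_identity(self, d1_epoch):
        f = stationary_pdf(d1_epoch, b_max=20, db=0.01)
        g = propagate_diagonal(f, d1_epoch, 0.0)
        np.testing.assert_array_equal(g.values, f.values)

    def test_stationarity_fixed_point(self, d1_epoch):
        f = stationary_pdf(d1_epoch, b_max=30, db=0.01, t=5.0)
        ep = EpochParams(0.0, np.inf, M=d1_epoch.M, gamma=d1_epoch.gamma)
        g = propagate_diagonal(f, ep, 2.0)
        np.testing.assert_allclose(
            g.values[:, 0, 0], 0.5 * np.exp(-g.b_grid / 2.0), atol=1e-12
        )

    def test_requires_contemporaneous_input(self, d1_epoch):
        f = stationary_pdf(d1_epoch, b_max=20, db=0.01, t=5.0)
        f = propagate_vertical(f, d1_epoch.L, 1.0)
        with pytest.raises(ValueError, match="contemporaneous"):
            propagate_diagonal(f, d1_epoch, 1.0)

    def test_mass_conserved_for_random_epochs(self, rng):
        # relies on int_0^{2 tau} (1/2) e^{-S b/2} G db = (I - e^{-S tau}) vec(1)
        for _ in range(5):
            d = int(rng.integers(1, 4))
            ep_new = random_epoch(d, rng, t_start=0.0, t_end=8.0)
            ep_old = random_epoch(d, rng, t_start=8.0)
            f = stationary_pdf(ep_old, db=0.02, t=8.0)
            g = propagate_diagonal(f, ep_new, 3.0)
            np.testing.assert_allclose(g.mass(), 1.0, atol=1e-4)

    def test_matches_upwind_pde_oracle(self, rng):
        ep_old = EpochParams(1.0, np.inf, M=[[0, 0.8], [0.6, 0]], gamma=[1.0, 2.0])
        ep_new = EpochParams(0.0, 1.0, M=[[0, 1.0], [0.4, 0]], gamma=[0.7, 1.3])
        db = 0.005
        f0 = stationary_pdf(ep_old, b_max=16, db=db, t=1.0)
        ours = propagate_diagonal(f0, ep_new, 1.0)
        oracle = upwind_diagonal_oracle(f0.values, db, ep_new.L, ep_new.gamma, 1.0)
        K = f0.values.shape[0]
        err = np.max(np.abs(ours.values[:K] - oracle))
        assert err < 5e-3
        # first-order convergence: halving the grid roughly halves the error
        db2 = db / 2
        f0b = stationary_pdf(ep_old, b_max=16, db=db2, t=1.0)
        ours2 = propagate_diagonal(f0b, ep_new, 1.0)
        oracle2 = upwind_diagonal_oracle(f0b.values, db2, ep_new.L, ep_new.gamma, 1.0)
        err2 = np.max(np.abs(ours2.values[: f0b.values.shape[0]] - oracle2))
        assert err2 < 0.65 * err

    def test_ergodic_convergence_to_stationary(self, sym2_epoch):
        # start far from equilibrium; total variation to f* shrinks with tau
        ep_start = EpochParams(10.0, np.inf, M=[[0, 0.1], [0.1, 0]], gamma=[3.0, 0.2])
        ep = EpochParams(-1e9, 10.0, M=sym2_epoch.M, gamma=sym2_epoch.gamma)
        f = stationary_pdf(ep_start, db=0.02, t=10.0)
        target = stationary_pdf(sym2_epoch, b_max=f.b_end, db=0.02)
        tvs = []
        for tau in (1.0, 3.0, 6.0):
            g = propagate_diagonal(f, ep, tau)
            K = min(g.values.shape[0], target.values.shape[0])
            tv = 0.5 * np.abs(g.values[:K] - target.values[:K]).sum(axis=0) * g.db
            tvs.append(tv.max())
        assert tvs[0] > tvs[1] > tvs[2]
        assert tvs[2] < 0.05


class TestChainsAndHorizontal:
    def test_mass_after_arbitrary_chain(self, three_epoch_model):
        for x, y in [(0.0, 0.0), (0.0, 1.0), (0.0, 2.0), (1.0, 2.0), (0.5, 1.5)]:
            f = pdf_at(three_epoch_model, x, y, db=0.0125)
            np.testing.assert_allclose(f.mass(), 1.0, atol=1e-4)

    def test_horizontal_residual_on_consistent_inputs(self, three_epoch_model):
        keys = [(0.0, 0.0), (0.0, 1.0), (0.0, 2.0), (1.0, 1.0), (1.0, 2.0), (2.0, 2.0)]
        f = {k: pdf_at(three_epoch_model, *k, db=0.0125) for k in keys}
        report = horizontal_pdf_check(f, three_epoch_model)
        assert set(report.residuals) == {
            "young_to_mixed_epoch0",
            "young_to_mixed_epoch1",
            "mixed_to_mixed",
        }
        assert report.max_residual < 1e-8

    def test_horizontal_detects_perturbation(self, three_epoch_model):
        keys = [(0.0, 0.0), (0.0, 1.0)]
        f = {k: pdf_at(three_epoch_model, *k, db=0.0125) for k in keys}
        f[(0.0, 0.0)].values[200, 0, 0] += 0.01
        report = horizontal_pdf_check(f, three_epoch_model)
        assert report.max_residual >= 0.005

    def test_degenerate_same_times_reduces_to_diagonal(self, sym2_epoch):
        # with a single epoch and slices inside it, the relation is the
        # plain diagonal propagator and the residual vanishes
        model = DemographicModel([sym2_epoch])
        keys = [(0.0, 0.0), (0.0, 0.5), (0.5, 0.5)]
        f = {k: pdf_at(model, *k, db=0.0125) for k in keys}
        report = horizontal_pdf_check(f, model)
        assert report.max_residual < 1e-8


class TestAgainstMonteCarlo:
    def test_two_random_scenarios_match_simulator(self, rng):
        # full 20-scenario sweep lives in the acceptance suite
        for _ in range(2):
            model = random_model(rng, d=2, n_epochs=2)
            x, y = 0.0, float(rng.integers(0, 3)) * 0.25
            i, j = rng.integers(0, 2, size=2)
            f = pdf_at(model, x, y, db=0.0125)
            b = simulate_branch_lengths(model, int(i), x, int(j), y, 40_000, seed=11)
            analytic_mean = f.mean()[i, j]
            se = b.std(ddof=1) / np.sqrt(len(b))
            assert abs(b.mean() - analytic_mean) < 3.5 * se

    def test_contemporaneous_reduces_to_twice_coalescence_time(self, sym2_epoch, rng):
        # B = 2 T for samples taken together: compare against a direct
        # coalescence-time CTMC built from a half-speed branch process
        model = DemographicModel([sym2_epoch])
        b = simulate_branch_lengths(model, 0, 0.0, 1, 0.0, 50_000, seed=3)
        t_half = b / 2.0
        f = pdf_at(model, 0.0, 0.0, db=0.0125)
        np.testing.assert_allclose(
            t_half.mean(), f.mean()[0, 1] / 2.0, atol=3 * t_half.std() / np.sqrt(len(b))
        )
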