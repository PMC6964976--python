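import numpy as np
import pytest

from mgrnnm import (
    FitState,
    MaskedProblem,
    MGRNNMParams,
    ShrinkageConfig,
    build_graph,
    mgrnnm_fit,
    mgrnnm_objective,
    predict,
    solve_right_sylvester,
    svs_solve,
    update_X,
)
from mgrnnm.datasets import SyntheticSpec, generate_synthetic
from mgrnnm.evaluation import aupr, training_problem
from mgrnnm.nnm import masked_residual, nuclear_norm


def random_graph(rng, k, normalized=False):
    A = rng.random((k, k))
    S = (A + A.T) / 2
    np.fill_diagonal(S, 0.0)
    return build_graph(S, normalized=normalized)


def random_problem(rng, n, m, obs=0.7):
    M = (rng.random((n, m)) < 0.3).astype(float)
    A = (rng.random((n, m)) < obs).astype(float)
    return MaskedProblem(M * A, A)


class TestSylvester:
    def test_mu_zero_returns_input(self, rng):
        C = rng.random((4, 3))
        np.testing.assert_array_equal(solve_right_sylvester(C, np.zeros((3, 3)), 2.0, 0.0), C)

    def test_zero_laplacian_returns_input(self, rng):
        C = rng.random((4, 3))
        L = random_graph(rng, 3).laplacian
        np.testing.assert_allclose(solve_right_sylvester(C, 0.0 * L, 2.0, 0.5), C)

    def test_matches_kronecker_vectorized_solve(self, rng):
        # vec(T) solves (nu I_kl + mu (L^T kron I_k)) vec(T) = nu vec(C)
        for _ in range(20):
            k, l = rng.integers(2, 8, size=2)
            C = rng.standard_normal((k, l))
            L = random_graph(rng, l).laplacian
            nu, mu = 2.0, 0.5
            T = solve_right_sylvester(C, L, nu, mu)
            K = nu * np.eye(k * l) + mu * np.kron(L.T, np.eye(k))
            T_ref = np.linalg.solve(K, nu * C.ravel(order="F")).reshape((k, l), order="F")
            np.testing.assert_allclose(T, T_ref, atol=1e-10)
            resid = np.linalg.norm(nu * T + mu * T @ L - nu * C)
            assert resid <= 1e-10 * max(np.linalg.norm(C), 1.0)

    def test_non_symmetric_laplacian_rejected(self, rng):
        L = rng.random((3, 3))
        with pytest.raises(ValueError, match="symmetric"):
            solve_right_sylvester(rng.random((2, 3)), L, 1.0, 1.0)


class TestObjective:
    def _state(self, X, Y, Z):
        return FitState(X=X, Y=Y, Z=Z)

    def test_all_zero_is_zero(self):
        p = MaskedProblem(np.zeros((2, 2)), np.ones((2, 2)))
        g = build_graph(np.zeros((2, 2)))
        s = self._state(np.zeros((2, 2)), np.zeros((2, 2)), np.zeros((2, 2)))
        assert mgrnnm_objective(s, p, g, g, MGRNNMParams()) == 0.0

    def test_reduces_to_plain_nnm_objective(self, rng):
        p = random_problem(rng, 5, 4)
        gd, gt = random_graph(rng, 5), random_graph(rng, 4)
        X = rng.random((5, 4))
        s = self._state(X, rng.random((5, 4)), rng.random((4, 5)))
        params = MGRNNMParams(lam=0.7, mu1=0, mu2=0, nu1=1e-300, nu2=1e-300)
        got = mgrnnm_objective(s, p, gd, gt, params)
        want = masked_residual(p, X) + 0.7 * nuclear_norm(X)
        assert got == pytest.approx(want, rel=1e-9)

    def test_matches_term_by_term_hand_computation(self):
        ones2 = np.ones((2, 2))
        p = MaskedProblem(ones2, ones2)
        Ld = build_graph(np.array([[0.0, 1.0], [1.0, 0.0]]), normalized=False)
        Lt = build_graph(np.array([[0.0, 1.0], [1.0, 0.0]]), normalized=False)
        X = Y = Z = ones2
        s = self._state(X, Y, Z)
        params = MGRNNMParams(lam=1.0, mu1=1.0, mu2=1.0, nu1=1.0, nu2=1.0)
        # residual 0; ||X||_* = 2; Tr(Z L Z^T) = 0 (constant rows);
        # split penalties 0
        assert mgrnnm_objective(s, p, Ld, Lt, params) == pytest.approx(2.0)


class TestUpdateX:
    def test_reduces_to_svs_when_penalties_vanish(self, rng):
        p = random_problem(rng, 8, 6)
        # update_X leaves the projection to mgrnnm_fit, so compare against
        # the unprojected SVS solution
        cfg = ShrinkageConfig(lam=0.5, tol=1e-12, max_iter=2000, nonneg=False)
        params = MGRNNMParams(lam=0.5, nu1=1e-12, nu2=1e-12,
                              inner=cfg)
        s = FitState(X=np.zeros((8, 6)), Y=rng.random((8, 6)), Z=rng.random((6, 8)))
        got = update_X(s, p, params)
        want = svs_solve(p, cfg)
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_closed_form_empty_mask(self, rng):
        Y, Zt = rng.random((5, 4)), rng.random((5, 4))
        p = MaskedProblem(np.zeros((5, 4)), np.zeros((5, 4)))
        params = MGRNNMParams(lam=1e-300, nu1=1.0, nu2=1.0,
                              inner=ShrinkageConfig(lam=0, tol=1e-14, max_iter=3000))
        s = FitState(X=np.zeros((5, 4)), Y=Y, Z=Zt.T)
        np.testing.assert_allclose(update_X(s, p, params), (Zt + Y) / 2, atol=1e-8)

    def test_closed_form_full_mask(self, rng):
        M, Y, Zt = rng.random((5, 4)), rng.random((5, 4)), rng.random((5, 4))
        p = MaskedProblem(M, np.ones((5, 4)))
        params = MGRNNMParams(lam=1e-300, nu1=1.0, nu2=1.0,
                              inner=ShrinkageConfig(lam=0, tol=1e-14, max_iter=3000))
        s = FitState(X=np.zeros((5, 4)), Y=Y, Z=Zt.T)
        np.testing.assert_allclose(update_X(s, p, params), (M + Zt + Y) / 3, atol=1e-8)


class TestFit:
    def test_reduction_to_plain_nnm(self, rng):
        for _ in range(5):
            p = random_problem(rng, 20, 15)
            gd, gt = random_graph(rng, 20), random_graph(rng, 15)
            params = MGRNNMParams(lam=0.5, mu1=0.0, mu2=0.0, tol=1e-12,
                                  max_iter=5000,
                                  inner=ShrinkageConfig(lam=0.5, tol=1e-12, max_iter=2000))
            st = mgrnnm_fit(p, gd, gt, params)
            ref = svs_solve(p, ShrinkageConfig(lam=0.5, tol=1e-14, max_iter=50000))
            err = np.linalg.norm(st.X - ref) / max(np.linalg.norm(ref), 1e-12)
            assert err < 1e-4

    def test_objective_history_non_increasing(self, rng):
        for _ in range(10):
            n, m = rng.integers(5, 15, size=2)
            p = random_problem(rng, n, m)
            gd, gt = random_graph(rng, n, True), random_graph(rng, m, True)
            st = mgrnnm_fit(p, gd, gt, MGRNNMParams(max_iter=60))
            h = np.array(st.objective_history)
            upticks = np.diff(h) / np.maximum(np.abs(h[:-1]), 1e-12)
            assert upticks.max(initial=0.0) <= 1e-8

    def test_converges_on_nr_sized_synthetic(self):
        res = generate_synthetic(SyntheticSpec(
            n_drugs=54, n_targets=26, latent_rank=3, interaction_density=0.064,
            label_flip_rate=0.0, seed=2))
        ds = res.dataset
        rng = np.random.default_rng(0)
        A = (rng.random(ds.interactions.shape) >= 0.1).astype(float)
        params = MGRNNMParams()
        problem, gd, gt = training_problem(ds, A, params)
        st = mgrnnm_fit(problem, gd, gt, params)
        assert st.converged and st.iterations_run <= 500

    def test_laplacian_shape_mismatch_rejected(self, rng):
        p = random_problem(rng, 5, 4)
        g5, g4 = random_graph(rng, 5), random_graph(rng, 4)
        with pytest.raises(ValueError, match="Laplacian"):
            mgrnnm_fit(p, g4, g5, MGRNNMParams())

    def test_transpose_symmetry(self, rng):
        p = random_problem(rng, 7, 5)
        gd, gt = random_graph(rng, 7, True), random_graph(rng, 5, True)
        params = MGRNNMParams(lam=0.3, mu1=0.4, mu2=0.2, nu1=1.5, nu2=0.8,
                              max_iter=40)
        st = mgrnnm_fit(p, gd, gt, params)
        pt = MaskedProblem(p.observed.T, p.mask.T)
        swapped = MGRNNMParams(lam=0.3, mu1=0.2, mu2=0.4, nu1=0.8, nu2=1.5,
                               max_iter=40)
        st_t = mgrnnm_fit(pt, gt, gd, swapped)
        np.testing.assert_allclose(st_t.X, st.X.T, atol=1e-12)

    def test_graph_regularization_helps_on_consistent_data(self):
        gains = []
        for seed in range(10):
            res = generate_synthetic(SyntheticSpec(
                n_drugs=60, n_targets=30, latent_rank=3,
                interaction_density=0.15, label_flip_rate=0.05, seed=seed))
            ds = res.dataset
            rng = np.random.default_rng(seed + 1000)
            A = (rng.random(ds.interactions.shape) >= 0.3).astype(float)
            test = A.ravel() == 0
            labels = ds.interactions.ravel()[test]
            scores = {}
            for name, (mu1, mu2) in {"mgrnnm": (0.5, 0.1), "nnm": (0.0, 0.0)}.items():
                params = MGRNNMParams(mu1=mu1, mu2=mu2)
                problem, gd, gt = training_problem(ds, A, params)
                st = mgrnnm_fit(problem, gd, gt, params)
                scores[name] = aupr(predict(st).ravel()[test], labels)
            gains.append(scores["mgrnnm"] - scores["nnm"])
        assert np.mean(gains) > 0


class TestPredict:
    def test_unfitted_state_rejected(self):
        s = FitState(X=np.zeros((2, 2)), Y=np.zeros((2, 2)), Z=np.zeros((2, 2)))
        with pytest.raises(ValueError, match="not fitted"):
            predict(s)

    def test_scores_finite_and_positives_rank_high(self, rng):
        res = generate_synthetic(SyntheticSpec(
            n_drugs=30, n_targets=20, latent_rank=2,
            interaction_density=0.2, label_flip_rate=0.0, seed=4))
        ds = res.dataset
        params = MGRNNMParams()
        problem, gd, gt = training_problem(ds, np.ones_like(ds.interactions), params)
        st = mgrnnm_fit(problem, gd, gt, params)
        X = predict(st)
        assert np.isfinite(X).all()
        assert X[ds.interactions == 1].mean() > X.mean()
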