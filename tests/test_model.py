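"""SSMA core: normalization, soft-thresholding, component fits, deflation,
penalty selection, multi-component models and persistence."""

import warnings

import numpy as np
import pytest

from ssma import SSMA, SupervisionWeights
from ssma.model import (
    OverPenalizedError,
    SSMAResults,
    deflate,
    fit_component,
    normalize_columns,
    objective_value,
    select_lambda,
    soft_threshold,
)

PLS = SupervisionWeights(1.0, 0.0, 0.0)


def _prep(rng, n=30, p=12, q=10):
    Xn, _, _ = normalize_columns(rng.standard_normal((n, p)))
    Yn, _, _ = normalize_columns(rng.standard_normal((n, q)))
    Z = rng.standard_normal(n)
    Z = (Z - Z.mean()) / Z.std(ddof=1)
    return Xn, Yn, Z


def _svd_pair(M):
    U, s, Vt = np.linalg.svd(M)
    wx, wy = U[:, 0], Vt[0]
    if wx[np.argmax(np.abs(wx))] < 0:
        wx, wy = -wx, -wy
    return wx, wy


class TestNormalizeColumns:
    def test_center_and_scale(self):
        out, means, scales = normalize_columns(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(out.ravel(), [-1, 0, 1])
        assert means[0] == pytest.approx(2.0)
        assert scales[0] == pytest.approx(1.0)

    def test_idempotent(self, rng):
        M, _, _ = normalize_columns(rng.standard_normal((20, 4)))
        again, _, _ = normalize_columns(M)
        assert np.allclose(M, again, atol=1e-12)

    def test_constant_column_left_unscaled(self):
        M = np.column_stack([np.full(5, 5.0), np.arange(5.0)])
        with pytest.warns(UserWarning, match="constant"):
            out, _, scales = normalize_columns(M)
        assert np.allclose(out[:, 0], 0.0)
        assert scales[0] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalize_columns(np.empty((0, 3)))


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "y,lam,expected",
        [(2.0, 0.5, 1.5), (-0.3, 0.5, 0.0), (-2.0, 0.5, -1.5), (0.7, 0.0, 0.7)],
    )
    def test_scalar_cases(self, y, lam, expected):
        assert soft_threshold(np.array([y]), lam)[0] == pytest.approx(expected)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.ones(3), -0.1)


class TestObjectiveValue:
    def test_zero_weights_zero_objective(self):
        z = np.zeros(5)
        assert objective_value(z, z, np.ones(5), z, z, PLS, 1.0, 1.0) == 0.0

    def test_pls_limit_is_inner_product(self, rng):
        t, u, Z = rng.standard_normal((3, 8))
        val = objective_value(t, u, Z, np.ones(2), np.ones(2), PLS, 0.0, 0.0)
        assert val == pytest.approx(t @ u, abs=1e-12)

    def test_term_by_term(self, rng):
        t, u, Z = rng.standard_normal((3, 6))
        wx, wy = rng.standard_normal((2, 4))
        sup = SupervisionWeights(0.5, 0.3, 0.2)
        expected = (0.5 * t @ u + 0.3 * t @ Z + 0.2 * u @ Z
                    - 2 * 0.7 * np.abs(wx).sum() - 2 * 0.4 * np.abs(wy).sum())
        assert objective_value(t, u, Z, wx, wy, sup, 0.7, 0.4) == pytest.approx(
            expected, abs=1e-12
        )

    def test_nonconformable(self):
        with pytest.raises(ValueError):
            objective_value(np.ones(4), np.ones(5), np.ones(4),
                            np.ones(2), np.ones(2), PLS, 0, 0)


class TestFitComponent:
    @pytest.mark.parametrize("seed", range(5))
    def test_unpenalized_pls_matches_svd(self, seed):
        rng = np.random.default_rng(seed)
        Xn, Yn, Z = _prep(rng)
        comp = fit_component(Xn, Yn, Z, PLS, tol=1e-12, max_iter=5000)
        wx, wy = _svd_pair(Xn.T @ Yn)
        assert np.abs(comp.w_x - wx).max() < 1e-6
        assert np.abs(comp.w_y - wy).max() < 1e-6
        assert np.linalg.norm(comp.w_x) == pytest.approx(1.0, abs=1e-10)
        assert np.linalg.norm(comp.w_y) == pytest.approx(1.0, abs=1e-10)

    def test_pure_outcome_supervision_closed_form(self, rng):
        # with mu = (0, 1, 0) the w_x update no longer depends on u
        Xn, Yn, Z = _prep(rng)
        comp = fit_component(Xn, Yn, Z, SupervisionWeights(0.0, 1.0, 0.0),
                             max_iter=50)
        direction = Xn.T @ Z
        direction /= np.linalg.norm(direction)
        assert np.abs(comp.w_x - direction).max() < 1e-10
        assert np.linalg.norm(comp.w_y) == pytest.approx(1.0, abs=1e-10)

    def test_single_informative_column(self, rng):
        X = np.zeros((30, 6))
        X[:, 3] = rng.standard_normal(30)
        X[:, 3] -= X[:, 3].mean()
        _, Yn, Z = _prep(rng)
        comp = fit_component(X, Yn, Z, PLS, max_iter=200)
        expected = np.zeros(6)
        expected[3] = 1.0
        assert np.allclose(np.abs(comp.w_x), expected)

    def test_objective_trace_nondecreasing(self, rng):
        for seed in range(4):
            r = np.random.default_rng(seed)
            Xn, Yn, Z = _prep(r)
            comp = fit_component(Xn, Yn, Z, SupervisionWeights(0.6, 0.2, 0.2),
                                 lambda_x=0.5, lambda_y=0.5, tol=1e-10,
                                 max_iter=2000)
            assert (np.diff(comp.objective_trace) >= -1e-8).all()

    def test_fixed_point_of_converged_state(self, rng):
        Xn, Yn, Z = _prep(rng)
        sup = SupervisionWeights(0.6, 0.2, 0.2)
        comp = fit_component(Xn, Yn, Z, sup, lambda_x=0.3, lambda_y=0.3,
                             tol=1e-13, max_iter=10000)
        # one more full update cycle by hand
        gx = Xn.T @ (sup.mu_xy * comp.u + sup.mu_xz * Z)
        wx = soft_threshold(gx, 0.3)
        wx /= np.linalg.norm(wx)
        t = Xn @ wx
        gy = Yn.T @ (sup.mu_xy * t + sup.mu_yz * Z)
        wy = soft_threshold(gy, 0.3)
        wy /= np.linalg.norm(wy)
        assert np.linalg.norm(np.abs(wx) - np.abs(comp.w_x)) < 1e-8
        assert np.linalg.norm(np.abs(wy) - np.abs(comp.w_y)) < 1e-8

    def test_sparsity_monotone_in_lambda(self, rng):
        Xn, Yn, Z = _prep(rng)
        nnz = []
        for lam in (0.0, 1.0, 2.0, 4.0):
            try:
                comp = fit_component(Xn, Yn, Z, PLS, lambda_x=lam,
                                     lambda_y=0.0, max_iter=500)
                nnz.append(np.count_nonzero(comp.w_x))
            except OverPenalizedError:
                nnz.append(0)
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))

    def test_overpenalized_raises_naming_block(self, rng):
        Xn, Yn, Z = _prep(rng)
        with pytest.raises(OverPenalizedError, match="lambda_x"):
            fit_component(Xn, Yn, Z, PLS, lambda_x=1e6)

    def test_nonconvergence_warns_not_raises(self, rng):
        Xn, Yn, Z = _prep(rng)
        with pytest.warns(UserWarning, match="did not converge"):
            comp = fit_component(Xn, Yn, Z, PLS, tol=1e-15, max_iter=1)
        assert not comp.converged


class TestDeflate:
    def test_rank_one_exact_removal(self, rng):
        s = rng.standard_normal(20)
        v = rng.standard_normal(7)
        resid, loading = deflate(np.outer(s, v), s)
        assert np.abs(resid).max() < 1e-10
        assert np.allclose(loading, v)

    def test_residual_orthogonal_to_score(self, rng):
        for _ in range(5):
            M = rng.standard_normal((30, 10))
            s = rng.standard_normal(30)
            resid, _ = deflate(M, s)
            assert np.abs(resid.T @ s).max() < 1e-9 * np.abs(M).max() * 30

    def test_orthogonal_score_zero_loading(self):
        M = np.outer(np.array([1.0, -1.0, 0.0, 0.0]), np.ones(3))
        _, loading = deflate(M, np.array([0.0, 0.0, 1.0, -1.0]))
        assert np.allclose(loading, 0.0)

    def test_zero_score_rejected(self):
        with pytest.raises(ValueError):
            deflate(np.ones((4, 2)), np.zeros(4))


class TestSelectLambda:
    def test_support_recovery_on_noiseless_toy(self, rng):
        # 5 variables, 2 truly nonzero: X and Y driven by one latent factor
        # through sparse loadings; BIC keeps the true support
        f = rng.standard_normal(40)
        X = np.outer(f, [1.0, -1.0, 0, 0, 0]) + 1e-3 * rng.standard_normal((40, 5))
        Y = np.outer(f, [0, 0, 1.0, 1.0, 0]) + 1e-3 * rng.standard_normal((40, 5))
        Xn, _, _ = normalize_columns(X)
        Yn, _, _ = normalize_columns(Y)
        Z = (f - f.mean()) / f.std(ddof=1)
        lx, ly = select_lambda(Xn, Yn, Z, PLS, grid_size=12)
        comp = fit_component(Xn, Yn, Z, PLS, lx, ly)
        assert set(np.flatnonzero(comp.w_x)) == {0, 1}
        assert set(np.flatnonzero(comp.w_y)) == {2, 3}

    def test_pure_noise_block_maximally_sparsified(self):
        # Y carries no structure: BIC should sit near the sparse end
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            f = rng.standard_normal(40)
            X = np.outer(f, [1.0, 1.0, -1.0, 0, 0, 0]) \
                + 0.01 * rng.standard_normal((40, 6))
            Y = rng.standard_normal((40, 8))
            Xn, _, _ = normalize_columns(X)
            Yn, _, _ = normalize_columns(Y)
            Z = (f - f.mean()) / f.std(ddof=1)
            lx, ly = select_lambda(Xn, Yn, Z, PLS, grid_size=12)
            comp = fit_component(Xn, Yn, Z, PLS, lx, ly)
            if np.count_nonzero(comp.w_y) <= 2:
                hits += 1
        assert hits >= 4

    def test_degenerate_grid_rejected(self, rng):
        Xn, Yn, Z = _prep(rng)
        with pytest.raises(ValueError):
            select_lambda(Xn, Yn, Z, PLS, grid_size=1)


class TestSSMAModel:
    def test_k1_reduces_to_fit_component(self, rng):
        X = rng.standard_normal((30, 12))
        Y = rng.standard_normal((30, 10))
        Z = rng.standard_normal(30)
        res = SSMA(X, Y, Z, n_components=1, lambda_x=0.0, lambda_y=0.0).fit()
        Xn, _, _ = normalize_columns(X)
        Yn, _, _ = normalize_columns(Y)
        Zc = (Z - Z.mean()) / Z.std(ddof=1)
        comp = fit_component(Xn, Yn, Zc, PLS)
        assert np.abs(res.components[0].w_x - comp.w_x).max() < 1e-8

    def test_score_orthogonality_across_components(self, rng):
        X = rng.standard_normal((30, 12))
        Y = rng.standard_normal((30, 10))
        Z = rng.standard_normal(30)
        res = SSMA(X, Y, Z, n_components=2, lambda_x=0.0, lambda_y=0.0).fit()
        t1, t2 = res.scores_t.T
        u1, u2 = res.scores_u.T
        scale = np.linalg.norm(t1) * np.linalg.norm(t2)
        assert abs(t1 @ t2) < 1e-8 * scale
        assert abs(u1 @ u2) < 1e-8 * (np.linalg.norm(u1) * np.linalg.norm(u2))

    def test_deflation_residual_orthogonality(self, rng):
        X = rng.standard_normal((25, 8))
        Y = rng.standard_normal((25, 7))
        Z = rng.standard_normal(25)
        model = SSMA(X, Y, Z, n_components=2, lambda_x=0.0, lambda_y=0.0)
        res = model.fit()
        Xd = model.X.copy()
        for comp in res.components:
            Xd = Xd - np.outer(comp.t, comp.p_loading)
            assert np.abs(Xd.T @ comp.t).max() < 1e-8 * np.abs(model.X).max() * 25

    def test_k_too_large_rejected(self, rng):
        X = rng.standard_normal((5, 3))
        Y = rng.standard_normal((5, 8))
        with pytest.raises(ValueError):
            SSMA(X, Y, rng.standard_normal(5), n_components=4)

    def test_constant_outcome_rejected(self, rng):
        X = rng.standard_normal((10, 4))
        Y = rng.standard_normal((10, 4))
        with pytest.raises(ValueError):
            SSMA(X, Y, np.ones(10))

    def test_transform_reproduces_training_scores(self, rng):
        X = rng.standard_normal((30, 12))
        Y = rng.standard_normal((30, 10))
        Z = rng.standard_normal(30)
        res = SSMA(X, Y, Z, n_components=2, lambda_x=0.0, lambda_y=0.0).fit()
        T, U = res.transform(X, Y)
        assert np.allclose(T, res.scores_t, atol=1e-10)
        assert np.allclose(U, res.scores_u, atol=1e-10)

    def test_transform_single_and_zero_subject(self, rng):
        X = rng.standard_normal((30, 12))
        Y = rng.standard_normal((30, 10))
        res = SSMA(X, Y, rng.standard_normal(30), n_components=1,
                   lambda_x=0.0, lambda_y=0.0).fit()
        T, U = res.transform(np.zeros(12), np.zeros(10))
        assert T.shape == (1, 1) and np.isfinite(T).all() and np.isfinite(U).all()
        with pytest.raises(ValueError):
            res.transform(np.zeros(13), np.zeros(10))

    @pytest.mark.parametrize("seed", [0, 3, 7])
    def test_supervision_shifts_scores_toward_outcome(self, seed, small_sim_k1):
        # single-component data: the fitted component tracks one latent
        # factor, so raising mu_XZ tilts its score toward the outcome
        # (with K > 1 truths the fitted component's identity can switch
        # between latent factors across mu, which breaks the comparison)
        basis, project = small_sim_k1
        from ssma import SimConfig, generate_dataset

        data = generate_dataset(SimConfig(image_shape=(40, 40),
                                          n_components=1, w_z=(1.0,),
                                          seed=seed))
        Xc, Yc = project(data)
        cors = []
        for mu_xz in (0.0, 0.25, 0.5):
            sup = SupervisionWeights.from_outcome_weights(mu_xz, 0.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = SSMA(Xc, Yc, data.Z, n_components=1, supervision=sup,
                           lambda_x=0.0, lambda_y=0.0).fit()
            cors.append(abs(np.corrcoef(res.components[0].t, data.Z)[0, 1]))
        assert cors[0] <= cors[1] + 1e-10 <= cors[2] + 2e-10

    def test_summary_mentions_each_component(self, rng):
        X = rng.standard_normal((20, 6))
        Y = rng.standard_normal((20, 5))
        res = SSMA(X, Y, rng.standard_normal(20), n_components=2,
                   lambda_x=0.0, lambda_y=0.0).fit()
        text = res.summary()
        assert "mu_XY" in text and text.count("\n") >= 6

    def test_save_load_roundtrip(self, rng, tmp_path):
        X = rng.standard_normal((25, 9))
        Y = rng.standard_normal((25, 7))
        res = SSMA(X, Y, rng.standard_normal(25), n_components=2,
                   lambda_x=0.0, lambda_y=0.0).fit()
        path = tmp_path / "model.npz"
        res.save(path)
        assert (tmp_path / "model.json").exists()
        loaded = SSMAResults.load(path)
        T0, U0 = res.transform(X, Y)
        T1, U1 = loaded.transform(X, Y)
        assert np.allclose(T0, T1) and np.allclose(U0, U1)


class TestSupervisionWeights:
    def test_simplex_enforced(self):
        with pytest.raises(ValueError):
            SupervisionWeights(0.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            SupervisionWeights(1.2, -0.1, -0.1)
        sw = SupervisionWeights.from_outcome_weights(0.25, 0.5)
        assert sw.mu_xy == pytest.approx(0.25)
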