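import numpy as np
import pytest
from scipy.linalg import subspace_angles

import gedi
from gedi import (
    CovariateBlock,
    FitConfig,
    GediError,
    GenePriorBlock,
    ObservationSet,
    fit,
    initialize,
    objective,
    update_block,
)
from gedi.fit import prior_quadratic
from gedi.observations import compute_posterior

from conftest import gaussian_observations, make_model


def rel_drops(trace):
    obj = np.asarray(trace.objective)
    if obj.size < 2:
        return np.array([0.0])
    return np.diff(obj) / (np.abs(obj[:-1]) + 1.0)


class TestInitialize:
    def test_noiseless_low_rank_exact(self, rng):
        G, N, K = 30, 80, 4
        Y = rng.normal(size=(G, K)) @ rng.normal(size=(K, N))
        obs = ObservationSet("gaussian", np.zeros(N, int), Y=Y)
        m = initialize(obs, FitConfig(K=K))
        resid = Y - gedi.decode_all(m)
        assert np.max(np.abs(resid)) < 1e-8

    def test_deterministic(self, rng):
        obs = gaussian_observations(rng)
        m1 = initialize(obs, FitConfig(K=3, seed=7))
        m2 = initialize(obs, FitConfig(K=3, seed=7))
        assert np.array_equal(m1.embeddings.B, m2.embeddings.B)
        assert np.array_equal(m1.manifold.Z_r, m2.manifold.Z_r)

    def test_svd_subspace(self, rng):
        Y = np.random.default_rng(3).normal(size=(100, 300))
        obs = ObservationSet("gaussian", np.zeros(300, int), Y=Y)
        m = initialize(obs, FitConfig(K=5))
        Yc = Y - Y.mean(axis=1, keepdims=True)
        Vt = np.linalg.svd(Yc, full_matrices=False)[2][:5]
        assert np.max(subspace_angles(Vt.T, m.embeddings.B.T)) < 1e-8

    def test_k_too_large(self, rng):
        obs = gaussian_observations(rng, G=10, N=12)
        with pytest.raises(GediError):
            initialize(obs, FitConfig(K=11))

    def test_poisson_intercepts_track_depth(self, rng):
        M = rng.poisson(3.0, size=(20, 50))
        obs = ObservationSet("poisson", np.zeros(50, int), M=M)
        m = initialize(obs, FitConfig(K=2, mode="poisson"))
        depth = np.maximum(M.sum(axis=0), 1)
        expected = np.log(depth) - np.log(np.median(depth))
        np.testing.assert_allclose(m.embeddings.s, expected)


class TestUpdateBlock:
    def test_delta_o_closed_form(self, rng):
        # hand-derived normal equation: shrunk per-sample residual mean
        m = make_model(rng, G=15, K=2, N=30, Q=3)
        m.S_delta_o = 0.7
        Y = rng.normal(size=(15, 30))
        obs = ObservationSet("gaussian", m.sample_map, Y=Y)
        out = update_block(m, obs, "delta_o")
        for i in range(3):
            cells = np.flatnonzero(m.sample_map == i)
            Z = m.manifold.Z_r + m.transforms.delta_Z[i]
            r = (
                Y[:, cells]
                - m.manifold.o_r[:, None]
                - Z @ m.embeddings.B[:, cells]
                - m.embeddings.s[cells][None, :]
            )
            expected = (cells.size * r.mean(axis=1)) / (cells.size + 1.0 / 0.7)
            np.testing.assert_allclose(out.transforms.delta_o[:, i], expected, atol=1e-10)

    def test_A_vanishing_prior_is_ols(self, rng):
        m = make_model(rng, with_prior=True, P=4, K=3)
        m.prior.S_A = 1e12
        m.prior.S_Z = 1.0
        obs = ObservationSet("gaussian", m.sample_map, Y=rng.normal(size=(m.G, m.N)))
        out = update_block(m, obs, "A")
        ols, *_ = np.linalg.lstsq(m.prior.C, m.manifold.Z_r, rcond=None)
        np.testing.assert_allclose(out.prior.A, ols, atol=1e-6)

    def test_R_o_zero_covariates(self, rng):
        m = make_model(rng, with_covariates=True)
        m.covariates.H[:] = 0.0
        obs = ObservationSet("gaussian", m.sample_map, Y=rng.normal(size=(m.G, m.N)))
        out = update_block(m, obs, "R_o")
        assert np.all(out.covariates.R_o == 0.0)

    def test_each_update_never_decreases_objective(self, rng):
        m = make_model(rng, with_prior=True, with_covariates=True)
        obs = ObservationSet("gaussian", m.sample_map, Y=rng.normal(size=(m.G, m.N)))
        blocks = ["s", "delta_o", "delta_Z", "o_r", "Z_r", "A", "R_o", "R_k", "sigma2"]
        current = m
        for block in blocks:
            before = objective(current, obs)
            current = update_block(current, obs, block)
            after = objective(current, obs)
            assert after >= before - 1e-8 * abs(before), block

    def test_unknown_block(self, rng):
        m = make_model(rng)
        obs = ObservationSet("gaussian", m.sample_map, Y=np.zeros((m.G, m.N)))
        with pytest.raises(GediError):
            update_block(m, obs, "nope")

    def test_prior_blocks_required(self, rng):
        m = make_model(rng)
        obs = ObservationSet("gaussian", m.sample_map, Y=np.zeros((m.G, m.N)))
        with pytest.raises(GediError):
            update_block(m, obs, "A")
        with pytest.raises(GediError):
            update_block(m, obs, "R_o")


class TestObjective:
    def test_zero_model_zero_data(self, rng):
        m = make_model(rng, with_prior=False)
        m.manifold.o_r[:] = 0
        m.manifold.Z_r[:] = 0
        m.transforms.delta_o[:] = 0
        m.transforms.delta_Z[:] = 0
        m.embeddings.s[:] = 0
        obs = ObservationSet("gaussian", m.sample_map, Y=np.zeros((m.G, m.N)))
        quad, df = prior_quadratic(m)
        assert quad == 0.0
        expected = -0.5 * (m.G * m.N + df) * np.log(m.sigma2)
        assert objective(m, obs) == pytest.approx(expected)

    def test_delta_Z_scaling_prior_increment(self, rng):
        m = make_model(rng)
        m.embeddings.B[:] = 0.0  # decouples delta_Z from the data term
        obs = ObservationSet("gaussian", m.sample_map, Y=gedi.decode_all(m))
        J1 = objective(m, obs)
        m2 = m.copy()
        m2.transforms.delta_Z *= 2.0
        J2 = objective(m2, obs)
        quad = np.sum(m.transforms.delta_Z**2) / m.S_delta_Z
        assert J1 - J2 == pytest.approx(3.0 * quad / (2 * m.sigma2))

    def test_term_by_term_recomputation(self, rng):
        m = make_model(rng, with_prior=True, with_covariates=True)
        Y = rng.normal(size=(m.G, m.N))
        obs = ObservationSet("gaussian", m.sample_map, Y=Y)
        # independent naive summation of every term
        sse = np.sum((Y - gedi.decode_all(m)) ** 2)
        pr = m.prior
        cov = m.covariates
        quad = np.sum((m.manifold.Z_r - pr.C @ pr.A) ** 2) / pr.S_Z
        quad += np.sum(pr.A**2) / pr.S_A
        quad += np.sum((m.transforms.delta_o - cov.R_o @ cov.H) ** 2) / cov.S_delta_o
        pmZ = np.einsum("kgl,lq->qgk", cov.R, cov.H)
        quad += np.sum((m.transforms.delta_Z - pmZ) ** 2) / cov.S_delta_Z
        quad += np.sum(cov.R_o**2) / cov.S_Ro
        quad += np.sum(cov.R**2) / cov.S_Rk
        G, K, Q, L, P = m.G, m.K, m.Q, cov.L, pr.P
        df = G * N_data(m) + G * K + P * K + G * Q + G * K * Q + G * L + K * G * L
        expected = -(sse + quad) / (2 * m.sigma2) - 0.5 * df * np.log(m.sigma2)
        assert objective(m, obs) == pytest.approx(expected)


def N_data(m):
    return m.N


class TestFit:
    def test_pca_limit(self, rng):
        # single sample, near prior-free: column-centred data so the
        # intercepts vanish at the optimum
        G, N, K = 120, 240, 4
        local = np.random.default_rng(11)
        Y0 = local.normal(size=(G, N))
        Y0 -= Y0.mean(axis=0, keepdims=True)
        U, S, Vt = np.linalg.svd(Y0, full_matrices=False)
        S[:K] *= 6.0
        Y = (U * S) @ Vt
        obs = ObservationSet("gaussian", np.zeros(N, int), Y=Y)
        cfg = FitConfig(
            K=K, S_Z=1e12, S_A=1e12, S_delta_o=1e-8, S_delta_Z=1e-8, tol=1e-12,
            max_sweeps=300,
        )
        m, _ = fit(obs, cfg)
        Yc = Y - Y.mean(axis=1, keepdims=True)
        Uk = np.linalg.svd(Yc, full_matrices=False)[0][:, :K]
        assert np.max(subspace_angles(Uk, m.manifold.Z_r)) < 1e-6

    def test_planted_delta_o_recovery(self, rng):
        # no library-size effects in the data, so the free intercepts are
        # disabled (they would otherwise absorb per-sample constants — a
        # genuine unidentifiability of translation vs intercept)
        G, N, K, Q = 50, 480, 3, 4
        local = np.random.default_rng(5)
        Z = local.normal(size=(G, K))
        B = local.normal(size=(K, N))
        smap = np.arange(N) % Q
        do = 1.5 * local.normal(size=(G, Q))
        Y = Z @ B + do[:, smap] + 0.2 * local.normal(size=(G, N))
        obs = ObservationSet("gaussian", smap, Y=Y)
        m, _ = fit(obs, FitConfig(K=K, update_s=False, S_delta_o=10.0))
        rec = m.transforms.delta_o - m.transforms.delta_o.mean(axis=1, keepdims=True)
        tru = do - do.mean(axis=1, keepdims=True)
        assert np.corrcoef(rec.ravel(), tru.ravel())[0, 1] > 0.99

    def test_identical_samples_exchangeable(self, rng):
        G, N, K = 30, 60, 2
        local = np.random.default_rng(9)
        half = local.normal(size=(G, N // 2))
        Y = np.hstack([half, half])
        smap = np.repeat([0, 1], N // 2)
        obs = ObservationSet("gaussian", smap, Y=Y)
        m, _ = fit(obs, FitConfig(K=K))
        diff = np.linalg.norm(m.transforms.delta_Z[0] - m.transforms.delta_Z[1])
        assert diff < 1e-3

    def test_monotone_objective_gaussian(self, rng):
        obs = gaussian_observations(rng, G=40, N=120, K=3, Q=3)
        _, trace = fit(obs, FitConfig(K=3))
        assert rel_drops(trace).min() > -1e-6

    def test_monotone_objective_poisson(self, rng):
        local = np.random.default_rng(21)
        G, N, K, Q = 25, 80, 2, 2
        lam = np.exp(local.normal(1.0, 0.5, size=(G, 1)) + 0.3 * local.normal(size=(G, N)))
        M = local.poisson(lam)
        obs = ObservationSet("poisson", np.arange(N) % Q, M=M)
        _, trace = fit(obs, FitConfig(K=K, mode="poisson", max_sweeps=25))
        assert rel_drops(trace).min() > -1e-6

    def test_monotone_objective_binomial(self, rng):
        local = np.random.default_rng(22)
        G, N, Q = 20, 60, 2
        total = local.poisson(3.0, size=(G, N))
        p = 1 / (1 + np.exp(-local.normal(0, 1, size=(G, 1)) * np.ones((1, N))))
        M1 = local.binomial(total, p)
        obs = ObservationSet("binomial", np.arange(N) % Q, M1=M1, M2=total - M1)
        _, trace = fit(obs, FitConfig(K=2, mode="binomial", max_sweeps=25))
        assert rel_drops(trace).min() > -1e-6

    def test_constraints_after_fit(self, rng):
        obs = gaussian_observations(rng, G=40, N=120, K=3, Q=3)
        m, _ = fit(obs, FitConfig(K=3))
        np.testing.assert_allclose(
            np.linalg.norm(m.embeddings.B, axis=1), 1.0, atol=1e-8
        )
        ZtZ = m.manifold.Z_r.T @ m.manifold.Z_r
        off = np.abs(ZtZ - np.diag(np.diag(ZtZ))).max()
        assert off <= 1e-8 * np.abs(np.diag(ZtZ)).max()
        norms = np.linalg.norm(m.manifold.Z_r, axis=0)
        assert np.all(np.diff(norms) <= 1e-9)  # sorted decreasing

    def test_gauge_renormalization_preserves_decodes(self, rng):
        obs = gaussian_observations(rng)
        m, _ = fit(obs, FitConfig(K=3))
        m.embeddings.B *= np.array([[2.0], [0.5], [1.5]])
        m.manifold.Z_r /= np.array([2.0, 0.5, 1.5])[None, :]
        m.transforms.delta_Z /= np.array([2.0, 0.5, 1.5])[None, None, :]
        before = gedi.decode_all(m)
        after = gedi.decode_all(gedi.renormalize_gauge(m))
        assert np.max(np.abs(before - after)) < 1e-10

    def test_seed_invariance_of_decoded_means(self, rng):
        obs = gaussian_observations(rng)
        m1, _ = fit(obs, FitConfig(K=3, seed=1))
        m2, _ = fit(obs, FitConfig(K=3, seed=99))
        diff = np.abs(gedi.decode_all(m1) - gedi.decode_all(m2))
        assert np.median(diff) < 1e-3

    def test_covariate_consistency(self, rng):
        # delta_o_i planted exactly as R_o @ h_i
        G, N, K, Q, L = 200, 360, 2, 12, 2
        local = np.random.default_rng(17)
        Z = local.normal(size=(G, K))
        B = local.normal(size=(K, N))
        smap = np.arange(N) % Q
        # centred covariates: a constant covariate would be confounded with
        # the unpenalized reference center o_r
        H = local.normal(size=(L, Q))
        H -= H.mean(axis=1, keepdims=True)
        R_o = local.normal(size=(G, L))
        Y = Z @ B + (R_o @ H)[:, smap] + 0.2 * local.normal(size=(G, N))
        obs = ObservationSet("gaussian", smap, Y=Y)
        cov = CovariateBlock(H=H, R_o=np.zeros((G, L)), R=np.zeros((K, G, L)))
        m, _ = fit(obs, FitConfig(K=K, update_s=False), covariates=cov)
        for l in range(L):
            r = np.corrcoef(m.covariates.R_o[:, l], R_o[:, l])[0, 1]
            assert r > 0.95, f"covariate {l}: r={r}"

    def test_fixed_embeddings_held_constant(self, rng):
        obs = gaussian_observations(rng, G=30, N=90, K=2, Q=2)
        init = initialize(obs, FitConfig(K=2))
        B0 = init.embeddings.B.copy()
        cfg = FitConfig(K=2, fixed_embeddings=B0, max_sweeps=20)
        m, _ = fit(obs, cfg)
        np.testing.assert_array_equal(m.embeddings.B, B0)

    def test_nonfinite_data_aborts(self, rng):
        Y = rng.normal(size=(10, 20))
        Y[0, 0] = np.nan
        obs = ObservationSet("gaussian", np.zeros(20, int), Y=Y)
        with pytest.raises(GediError):
            fit(obs, FitConfig(K=2, max_sweeps=3))

    def test_prior_pull(self, rng):
        # factors defined by disjoint gene sets present in C
        G, K, N = 120, 4, 300
        local = np.random.default_rng(31)
        C = np.zeros((G, K))
        for p in range(K):
            C[p * 30 : (p + 1) * 30, p] = 1.0
        # distinct factor scales: the axis prior is rotation-invariant inside
        # span(C), so alignment to individual sets needs separated variances
        B = local.normal(size=(K, N)) * np.array([4.0, 3.0, 2.2, 1.5])[:, None]
        Y = C @ B + 0.2 * local.normal(size=(G, N))
        obs = ObservationSet("gaussian", np.zeros(N, int), Y=Y)
        prior = GenePriorBlock(C=C, A=np.zeros((K, K)), S_Z=1.0, S_A=1.0)
        # no library-size effects planted; the free intercept would absorb
        # the mean of the set scores (the sets tile all genes here)
        m, _ = fit(obs, FitConfig(K=K, S_Z=3.0, update_s=False), prior=prior)
        matched = {int(np.argmax(np.abs(m.prior.A[:, k]))) for k in range(K)}
        act = gedi.activities(m)
        hits = sum(
            1
            for p in range(K)
            if p in matched and abs(np.corrcoef(act[p], B[p])[0, 1]) > 0.9
        )
        assert hits >= int(np.ceil(0.9 * K))


class TestFitConfigValidation:
    def test_bad_hyperparameters(self):
        with pytest.raises(GediError):
            FitConfig(K=0)
        with pytest.raises(GediError):
            FitConfig(K=2, tol=0.0)
        with pytest.raises(GediError):
            FitConfig(K=2, S_Z=-1.0)
        with pytest.raises(GediError):
            FitConfig(K=2, mode="negbin")
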