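"""GRM, GBLUP against a dense-inverse oracle, and REML behavior."""

import numpy as np
import pytest

from troutsim import (
    EvaluationData,
    VarianceComponents,
    build_genetic_map,
    compute_grm,
    estimate_varcomp_reml,
    expected_bias,
    generate_founder_population,
    sample_gametes,
    solve_bivariate_gblup,
    solve_gblup,
    solve_univariate_gblup,
)

# ---------------------------------------------------------------------------
# oracles


def dense_gblup_oracle(data, G, vc):
    """Independent GLS solution via the full phenotypic covariance matrix."""
    n = data.n_animals
    N = data.n_records
    Sg = vc.genetic_matrix
    Z = np.zeros((N, 2 * n))
    for r in range(N):
        Z[r, data.env[r] * n + data.animal[r]] = 1.0
    Gbig = np.kron(Sg, G)
    R = np.diag(np.where(data.env == 0, vc.sigma2_eB, vc.sigma2_eC).astype(float))
    V = Z @ Gbig @ Z.T + R
    labels, idx = np.unique(np.stack([data.env, data.year]), axis=1, return_inverse=True)
    X = np.zeros((N, labels.shape[1]))
    X[np.arange(N), idx.ravel()] = 1.0
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ data.y)
    u = Gbig @ Z.T @ Vi @ (data.y - X @ beta)
    return np.column_stack([u[:n], u[n:]])


def dense_reml_m2ll_oracle(data, G, theta):
    """-2 restricted log-likelihood from the V-form expression."""
    s2gB, cov, s2gC, s2eB, s2eC = theta
    n, N = data.n_animals, data.n_records
    Sg = np.array([[s2gB, cov], [cov, s2gC]])
    Z = np.zeros((N, 2 * n))
    for r in range(N):
        Z[r, data.env[r] * n + data.animal[r]] = 1.0
    V = Z @ np.kron(Sg, G) @ Z.T + np.diag(
        np.where(data.env == 0, s2eB, s2eC).astype(float)
    )
    labels, idx = np.unique(np.stack([data.env, data.year]), axis=1, return_inverse=True)
    X = np.zeros((N, labels.shape[1]))
    X[np.arange(N), idx.ravel()] = 1.0
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi)
    return (
        np.linalg.slogdet(V)[1] + np.linalg.slogdet(XtViX)[1] + float(data.y @ P @ data.y)
    )


def _family_data(n_fam=40, fam_size=6, rg=0.5, h2=0.3, seed=0, n_markers=400):
    """Records simulated under the bivariate model on a family-structured GRM."""
    r = np.random.default_rng(seed)
    gmap = build_genetic_map(5, 500.0, n_markers, r)
    founders = generate_founder_population(60, gmap, 0.1, 0.5, 5, r)
    p = founders.sum(axis=(0, 1)) / 120.0
    rep_s = np.repeat(r.choice(30, n_fam), fam_size)
    rep_d = np.repeat(30 + r.choice(30, n_fam), fam_size)
    hap = np.stack(
        [sample_gametes(founders[rep_s], gmap, r), sample_gametes(founders[rep_d], gmap, r)],
        axis=1,
    )
    n = hap.shape[0]
    G = compute_grm(hap.sum(axis=1).astype(float), p)
    Sg = np.array([[1, rg], [rg, 1]])
    u = np.linalg.cholesky(G + 1e-6 * np.eye(n)) @ r.standard_normal((n, 2)) @ np.linalg.cholesky(Sg).T
    env = r.integers(0, 2, n)
    year = r.integers(0, 2, n)
    se2 = (1 - h2) / h2
    y = u[np.arange(n), env] + r.normal(0, np.sqrt(se2), n)
    data = EvaluationData(y=y, animal=np.arange(n), env=env, year=year, n_animals=n)
    return data, G, u


def _toy_data(n=14, seed=3, both_envs=True):
    r = np.random.default_rng(seed)
    p = r.uniform(0.2, 0.5, 60)
    geno = r.binomial(2, p, size=(n, 60)).astype(float)
    G = compute_grm(geno, p)
    env = r.integers(0, 2, n) if both_envs else np.zeros(n, dtype=int)
    year = r.integers(0, 2, n)
    y = r.standard_normal(n)
    return EvaluationData(y=y, animal=np.arange(n), env=env, year=year, n_animals=n), G


# ---------------------------------------------------------------------------
# GRM


class TestGRM:
    def test_single_locus_examples(self):
        # (2 - 1)^2 / (2 * 0.25) = 2; heterozygote centered to zero
        G2 = compute_grm(np.array([[2.0]]), np.array([0.5]))
        assert G2[0, 0] == pytest.approx(2.0)
        G1 = compute_grm(np.array([[1.0]]), np.array([0.5]))
        assert G1[0, 0] == pytest.approx(0.0)

    def test_founder_mean_diagonal_near_one(self, small_map):
        founders = generate_founder_population(150, small_map, 0.1, 0.5, 5, seed=8)
        p = founders.sum(axis=(0, 1)) / 300.0
        G = compute_grm(founders.sum(axis=1).astype(float), p)
        assert np.allclose(G, G.T)
        assert abs(np.mean(np.diag(G)) - 1.0) < 0.05

    def test_fixed_loci_dropped_and_empty_error(self):
        geno = np.array([[2.0, 1.0], [0.0, 1.0]])
        G_drop = compute_grm(geno, np.array([1.0, 0.5]))
        G_ref = compute_grm(geno[:, 1:], np.array([0.5]))
        np.testing.assert_allclose(G_drop, G_ref)
        with pytest.raises(ValueError):
            compute_grm(geno, np.array([0.0, 1.0]))


# ---------------------------------------------------------------------------
# GBLUP


class TestGBLUP:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_dense_inverse_oracle(self, seed):
        data, G = _toy_data(seed=seed)
        vc = VarianceComponents.from_true(0.5, 0.3)
        res = solve_bivariate_gblup(data, G, vc)
        oracle = dense_gblup_oracle(data, G, vc)
        np.testing.assert_allclose(res.gebv, oracle, atol=1e-8)

    def test_record_space_and_mme_paths_agree(self):
        """The record-space GLS shortcut and the explicit mixed-model
        equations give the same GEBV."""
        from troutsim.evaluation import invert_grm

        data, G = _toy_data(seed=4)
        vc = VarianceComponents.from_true(0.8, 0.1)
        fast = solve_gblup(data, G, vc)
        G_inv, _ = invert_grm(G)
        slow = solve_gblup(data, G, vc, G_inv=G_inv)
        np.testing.assert_allclose(fast.gebv, slow.gebv, atol=1e-8)
        np.testing.assert_allclose(fast.fixed_effects, slow.fixed_effects, atol=1e-8)

    def test_univariate_matches_oracle(self):
        data, G = _toy_data(seed=5, both_envs=False)
        vc = VarianceComponents.from_true(0.5, 0.3)
        res = solve_univariate_gblup(data, G, vc)
        oracle = dense_gblup_oracle(data, G, vc)
        np.testing.assert_allclose(res.gebv[:, 0], oracle[:, 0], atol=1e-8)
        assert np.isnan(res.gebv[:, 1]).all()

    def test_no_signal_gives_zero_gebv(self):
        data, G = _toy_data(seed=2)
        y = np.where(data.env == 0, 1.0, -2.0) + data.year * 3.0
        flat = EvaluationData(
            y=y, animal=data.animal, env=data.env, year=data.year, n_animals=data.n_animals
        )
        res = solve_gblup(flat, G, VarianceComponents.from_true(0.5, 0.3))
        np.testing.assert_allclose(res.gebv[~np.isnan(res.gebv)], 0.0, atol=1e-9)

    def test_year_class_translation_invariance(self):
        data, G = _toy_data(seed=7)
        vc = VarianceComponents.from_true(0.5, 0.3)
        base = solve_gblup(data, G, vc).gebv
        shifted_y = data.y + np.where((data.env == 0) & (data.year == 1), 7.5, 0.0)
        shifted = EvaluationData(
            y=shifted_y, animal=data.animal, env=data.env, year=data.year, n_animals=data.n_animals
        )
        np.testing.assert_allclose(solve_gblup(shifted, G, vc).gebv, base, atol=1e-9)

    def test_noise_free_limit_recovers_centered_phenotypes(self):
        data, G = _toy_data(seed=9, both_envs=False)
        vc = VarianceComponents(1.0, 1.0, 0.5, 1e-10, 1e-10)
        res = solve_gblup(data, G, vc)
        cls = data.year  # single env: class = year
        centered = data.y - np.array([res.fixed_effects[c] for c in cls])
        np.testing.assert_allclose(res.gebv[:, 0], centered, atol=1e-4)

    def test_C_gebv_of_B_animals_through_covariance(self):
        """Fish recorded only in B receive a C-trait GEBV via the genetic
        covariance with the C-recorded reference fish."""
        data, G = _toy_data(seed=11)
        vc = VarianceComponents.from_true(0.8, 0.3)
        res = solve_bivariate_gblup(data, G, vc)
        b_animals = data.animal[data.env == 0]
        assert np.all(np.isfinite(res.gebv[b_animals, 1]))
        assert np.corrcoef(res.gebv[b_animals, 0], res.gebv[b_animals, 1])[0, 1] > 0.5

    def test_bivariate_requires_both_envs(self):
        data, G = _toy_data(seed=1, both_envs=False)
        with pytest.raises(ValueError):
            solve_bivariate_gblup(data, G, VarianceComponents.from_true(0.5, 0.3))


# ---------------------------------------------------------------------------
# REML


class TestREML:
    def test_parameter_recovery_within_mc_error(self):
        """Estimates under random genotyping are unbiased: with the GRM held
        fixed and traits redrawn under the model, each component's mean over
        replicates sits within 2 MC standard errors of the truth."""
        truth = np.array([1.0, 1.0, 0.5, 7 / 3, 7 / 3])
        rg, h2 = 0.5, 0.3
        _, G, _ = _family_data(n_fam=60, fam_size=8, rg=rg, h2=h2, seed=0, n_markers=500)
        n = G.shape[0]
        L = np.linalg.cholesky(G + 1e-8 * np.eye(n))
        cS = np.linalg.cholesky(np.array([[1, rg], [rg, 1]]))
        se2 = (1 - h2) / h2
        ests = []
        for rep in range(12):
            r = np.random.default_rng(1000 + rep)
            u = L @ r.standard_normal((n, 2)) @ cS.T
            env = r.integers(0, 2, n)
            year = r.integers(0, 2, n)
            y = u[np.arange(n), env] + r.normal(0, np.sqrt(se2), n)
            data = EvaluationData(y=y, animal=np.arange(n), env=env, year=year, n_animals=n)
            res = estimate_varcomp_reml(data, G)
            assert res.converged
            vc = res.varcomp
            ests.append(
                [vc.sigma2_gB, vc.sigma2_gC, vc.sigma_gBgC, vc.sigma2_eB, vc.sigma2_eC]
            )
        E = np.array(ests)
        mc_se = E.std(axis=0, ddof=1) / np.sqrt(len(E))
        assert np.all(np.abs(E.mean(axis=0) - truth) < 2 * mc_se + 0.05)

    def test_univariate_reml_runs_and_partitions_variance(self):
        """Single-environment records: the univariate REML converges and the
        estimated total variance tracks the phenotypic variance."""
        _, G, u = _family_data(n_fam=30, fam_size=6, seed=4)
        n = G.shape[0]
        r = np.random.default_rng(0)
        y = u[:, 0] + r.normal(0, np.sqrt(7 / 3), n)
        data = EvaluationData(
            y=y, animal=np.arange(n), env=np.zeros(n, dtype=int),
            year=np.zeros(n, dtype=int), n_animals=n,
        )
        res = estimate_varcomp_reml(data, G)
        assert res.converged
        vc = res.varcomp
        assert vc.sigma2_gB > 0 and vc.sigma2_eB > 0
        assert np.isnan(vc.sigma2_gC)
        total = vc.sigma2_gB + vc.sigma2_eB
        assert total == pytest.approx(np.var(y), rel=0.35)

    @pytest.mark.parametrize("seed", [0, 1, 4])
    def test_record_space_and_mme_reml_agree(self, seed):
        """The record-space and mixed-model-equation REML formulations reach
        the same interior optimum (on the |r_g| = 1 boundary the likelihood
        ridge is flat and only the likelihood values are comparable)."""
        data, G, _ = _family_data(n_fam=40, fam_size=8, rg=0.3, seed=seed)
        r1 = estimate_varcomp_reml(data, G, method="record")
        r2 = estimate_varcomp_reml(data, G, method="mme")
        assert r1.minus2_loglik == pytest.approx(r2.minus2_loglik, abs=1e-4)
        for name in ("sigma2_gB", "sigma2_gC", "sigma_gBgC", "sigma2_eB", "sigma2_eC"):
            assert getattr(r1.varcomp, name) == pytest.approx(
                getattr(r2.varcomp, name), abs=1e-3
            )

    def test_minus2_loglik_matches_dense_oracle(self):
        data, G, _ = _family_data(n_fam=8, fam_size=4, seed=1)
        res = estimate_varcomp_reml(data, G, max_iter=5)
        vc = res.varcomp
        theta = np.array(
            [vc.sigma2_gB, vc.sigma_gBgC, vc.sigma2_gC, vc.sigma2_eB, vc.sigma2_eC]
        )
        assert res.minus2_loglik == pytest.approx(
            dense_reml_m2ll_oracle(data, G, theta), abs=1e-6
        )

    def test_estimate_is_a_likelihood_maximum(self):
        data, G, _ = _family_data(n_fam=10, fam_size=4, seed=2)
        res = estimate_varcomp_reml(data, G)
        vc = res.varcomp
        theta = np.array(
            [vc.sigma2_gB, vc.sigma_gBgC, vc.sigma2_gC, vc.sigma2_eB, vc.sigma2_eC]
        )
        at_opt = dense_reml_m2ll_oracle(data, G, theta)
        for k in range(5):
            for d in (-0.15, 0.15):
                pert = theta.copy()
                pert[k] += d
                if pert[k] <= 0 and k != 1:
                    continue
                if abs(pert[1]) >= np.sqrt(pert[0] * pert[2]):
                    continue
                assert dense_reml_m2ll_oracle(data, G, pert) >= at_opt - 1e-6


class TestExpectedBias:
    def test_values(self):
        vc_eq = VarianceComponents(1.0, 1.0, 0.5, 2.0, 2.0)
        assert expected_bias(0.5, vc_eq, has_C_records=False) == pytest.approx(0.5)
        assert expected_bias(0.5, vc_eq, has_C_records=True) == pytest.approx(1.0)
        vc_uneq = VarianceComponents(1.0, 4.0, 0.5, 2.0, 2.0)
        assert expected_bias(0.8, vc_uneq, has_C_records=False) == pytest.approx(1.6)


def test_varcomp_validation():
    with pytest.raises(ValueError):
        VarianceComponents(1.0, 1.0, 1.5, 1.0, 1.0).validate()  # not PSD
    with pytest.raises(ValueError):
        VarianceComponents(1.0, 1.0, 0.2, -1.0, 1.0).validate()
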