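"""Mixed-model machinery: kinship construction, REML estimation against a
dense grid-search oracle and statsmodels, and the three POE tests."""

import numpy as np
import pytest
from scipy import stats

import poescan as ps
from poescan.lmm import LmmError

from conftest import fit_poe, poe_design_matrix


def reml_loglik_dense(lam, y, X, C):
    """Independent REML criterion: explicit V = lam*C + I, dense algebra."""
    n, p = X.shape
    V = lam * C + np.eye(n)
    Vi = np.linalg.inv(V)
    A = X.T @ Vi @ X
    beta = np.linalg.solve(A, X.T @ Vi @ y)
    r = y - X @ beta
    rss = float(r @ Vi @ r)
    s2 = rss / (n - p)
    _, ldV = np.linalg.slogdet(V)
    _, ldA = np.linalg.slogdet(A)
    return -0.5 * ((n - p) * (np.log(2 * np.pi * s2) + 1.0) + ldV + ldA)


def sibpair_families(n_pairs):
    fams = []
    for i in range(n_pairs):
        fid = f"S{i:04d}"
        fams.append(
            ps.Family(
                fid,
                ps.Individual(f"{fid}_F", fid, "father", "male"),
                ps.Individual(f"{fid}_M", fid, "mother", "female"),
                [
                    ps.Individual(f"{fid}_O1", fid, "offspring", "male"),
                    ps.Individual(f"{fid}_O2", fid, "offspring", "female"),
                ],
            )
        )
    return fams


def simulate_gaussian(families, kinship, sigma_b2, sigma_e2, beta, rng,
                      n_cov=2):
    """Draw (y, X, ids) from the mixed model with known coefficients."""
    ids = kinship.offspring_ids
    n = len(ids)
    X = np.column_stack([rng.binomial(1, 0.4, n), rng.normal(size=(n, n_cov))])
    C = kinship.dense()
    L = np.linalg.cholesky(C + 1e-10 * np.eye(n))
    y = (
        0.3
        + X @ np.asarray(beta)
        + np.sqrt(sigma_b2) * (L @ rng.standard_normal(n))
        + rng.normal(0.0, np.sqrt(sigma_e2), n)
    )
    return y, X, ids


class TestBuildKinship:
    def test_fullsib_block(self, trio_family):
        kin = ps.build_kinship([trio_family()])
        np.testing.assert_allclose(kin.dense(), [[1.0, 0.5], [0.5, 1.0]])

    def test_mz_twin_block(self, trio_family):
        kin = ps.build_kinship([trio_family(zygosity="MZ")])
        np.testing.assert_allclose(kin.dense(), [[1.0, 1.0], [1.0, 1.0]])

    def test_dz_and_unknown_twins_use_sib_corr(self, trio_family):
        kin = ps.build_kinship([trio_family(zygosity="DZ")])
        assert kin.dense()[0, 1] == 0.5

    def test_singleton_block(self, trio_family):
        kin = ps.build_kinship([trio_family(n_offspring=1)])
        np.testing.assert_allclose(kin.dense(), [[1.0]])

    def test_zero_between_families(self, trio_family):
        kin = ps.build_kinship([trio_family("A"), trio_family("B")])
        C = kin.dense()
        assert C[0, 2] == 0.0 and C[1, 3] == 0.0

    def test_psd_and_symmetric(self, small_dataset):
        C = ps.build_kinship(small_dataset.families).dense()
        np.testing.assert_allclose(C, C.T)
        assert np.linalg.eigvalsh(C).min() > -1e-10

    def test_invalid_corr_rejected(self, trio_family):
        with pytest.raises(LmmError):
            ps.build_kinship([trio_family()], sib_corr=1.5)

    def test_decomposition_reconstructs_dense(self, small_dataset):
        kin = ps.build_kinship(small_dataset.families)
        ids = kin.offspring_ids
        dec = kin.decomposition(tuple(ids))
        # rotate the identity: U' ; then U diag(s) U' must equal C
        Ut = dec.rotate(np.eye(len(ids)))
        C_rebuilt = Ut.T @ np.diag(dec.eigenvalues) @ Ut
        np.testing.assert_allclose(C_rebuilt, kin.dense(), atol=1e-10)


class TestRemlFit:
    def test_identity_kinship_gives_ols_coefficients(self):
        rng = np.random.default_rng(0)
        n = 120
        X = rng.normal(size=(n, 3))
        y = 1.0 + X @ [0.5, -0.2, 0.0] + rng.normal(size=n)
        est = ps.KinshipMixedLM(kinship=None).fit(X, y)
        Xd = np.column_stack([np.ones(n), X])
        beta_ols = np.linalg.lstsq(Xd, y, rcond=None)[0]
        np.testing.assert_allclose(
            np.r_[est.intercept_, est.coef_], beta_ols, atol=1e-10
        )

    def test_matches_grid_search_oracle_small_instance(self):
        rng = np.random.default_rng(1)
        fams = sibpair_families(20)  # 40 offspring
        kin = ps.build_kinship(fams)
        y, X, ids = simulate_gaussian(fams, kin, 0.5, 1.0, [0.4, 0.1, 0.0], rng)
        est = ps.KinshipMixedLM(kinship=kin).fit(X, y, sample_ids=ids)
        C = kin.dense()
        Xd = np.column_stack([np.ones(len(y)), X])
        grid = np.linspace(0.0, 10.0, 4001)
        oracle = max(reml_loglik_dense(l, y, Xd, C) for l in grid)
        assert est.loglik_reml_ == pytest.approx(oracle, abs=1e-4)
        assert est.loglik_reml_ >= oracle - 1e-4

    def test_matches_statsmodels_random_intercept_on_mz_families(self):
        # with every family an MZ pair, C is block-of-ones: identical to a
        # shared family intercept, which statsmodels MixedLM can fit
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        fams = []
        for i in range(60):
            fid = f"Z{i:03d}"
            fams.append(
                ps.Family(
                    fid,
                    ps.Individual(f"{fid}_F", fid, "father", "male"),
                    ps.Individual(f"{fid}_M", fid, "mother", "female"),
                    [
                        ps.Individual(f"{fid}_O1", fid, "offspring", "male",
                                      zygosity="MZ"),
                        ps.Individual(f"{fid}_O2", fid, "offspring", "male",
                                      zygosity="MZ"),
                    ],
                )
            )
        kin = ps.build_kinship(fams)
        y, X, ids = simulate_gaussian(fams, kin, 0.6, 1.0, [0.4, 0.1, 0.0], rng)
        est = ps.KinshipMixedLM(kinship=kin).fit(X, y, sample_ids=ids)

        groups = np.repeat(np.arange(60), 2)
        Xd = sm.add_constant(X)
        sm_fit = sm.MixedLM(y, Xd, groups=groups).fit(reml=True)
        np.testing.assert_allclose(
            np.r_[est.intercept_, est.coef_], sm_fit.fe_params, atol=1e-5
        )
        np.testing.assert_allclose(
            np.sqrt(np.diag(est.cov_beta_)), sm_fit.bse_fe, rtol=5e-3
        )
        assert est.sigma_b2_ == pytest.approx(
            float(np.asarray(sm_fit.cov_re)[0, 0]), abs=1e-4
        )
        assert est.sigma_e2_ == pytest.approx(sm_fit.scale, abs=1e-4)

    def test_eigen_path_agrees_with_direct_gls_solve(self):
        rng = np.random.default_rng(3)
        fams = sibpair_families(40)  # 80 offspring
        kin = ps.build_kinship(fams)
        y, X, ids = simulate_gaussian(fams, kin, 0.5, 1.0, [0.3, 0.0, 0.0], rng)
        est = ps.KinshipMixedLM(kinship=kin).fit(X, y, sample_ids=ids)
        # direct solve at the fitted lambda via explicit inverse
        C = kin.dense()
        V = est.lambda_ * C + np.eye(len(y))
        Vi = np.linalg.inv(V)
        Xd = np.column_stack([np.ones(len(y)), X])
        A = Xd.T @ Vi @ Xd
        beta = np.linalg.solve(A, Xd.T @ Vi @ y)
        np.testing.assert_allclose(est.beta_, beta, atol=1e-8)
        np.testing.assert_allclose(
            est.cov_beta_, est.sigma_e2_ * np.linalg.inv(A), atol=1e-8
        )

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        fams = sibpair_families(30)
        kin = ps.build_kinship(fams)
        y, X, ids = simulate_gaussian(fams, kin, 0.4, 1.0, [0.3, 0.1, -0.1], rng)
        X2 = X[:, :2]
        f1 = ps.fit_lmm(y, X2, kin, sample_ids=ids, model="poe")
        f2 = ps.fit_lmm(3.0 * y, X2, kin, sample_ids=ids, model="poe")
        assert f2.beta1 == pytest.approx(3.0 * f1.beta1, rel=1e-6)
        t1, t2 = ps.poe_tests(f1), ps.poe_tests(f2)
        assert t2.p_paternal == pytest.approx(t1.p_paternal, rel=1e-6)
        assert t2.p_diff == pytest.approx(t1.p_diff, rel=1e-6)
        np.testing.assert_allclose(
            np.array(t2.ci_paternal), 3.0 * np.array(t1.ci_paternal), rtol=1e-6
        )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        fams = sibpair_families(25)
        kin = ps.build_kinship(fams)
        y, X, ids = simulate_gaussian(fams, kin, 0.5, 1.0, [0.3, 0.1, 0.0], rng)
        est1 = ps.KinshipMixedLM(kinship=kin).fit(X, y, sample_ids=ids)
        perm = rng.permutation(len(ids))
        est2 = ps.KinshipMixedLM(kinship=kin).fit(
            X[perm], y[perm], sample_ids=[ids[i] for i in perm]
        )
        np.testing.assert_allclose(est1.beta_, est2.beta_, atol=1e-8)
        assert est1.sigma_b2_ == pytest.approx(est2.sigma_b2_, abs=1e-8)

    def test_rank_deficient_design_names_columns(self):
        rng = np.random.default_rng(6)
        n = 50
        x = rng.normal(size=n)
        X = np.column_stack([x, x, rng.normal(size=n)])
        with pytest.raises(LmmError, match="rank deficient"):
            ps.KinshipMixedLM().fit(X, rng.normal(size=n))

    def test_boundary_sigma_b2_zero_reached(self):
        # independent singletons: no family variance to find
        rng = np.random.default_rng(7)
        n = 200
        fams = []
        for i in range(n):
            fid = f"G{i:03d}"
            fams.append(
                ps.Family(
                    fid,
                    ps.Individual(f"{fid}_F", fid, "father", "male"),
                    ps.Individual(f"{fid}_M", fid, "mother", "female"),
                    [ps.Individual(f"{fid}_O", fid, "offspring", "male")],
                )
            )
        kin = ps.build_kinship(fams)
        y, X, ids = simulate_gaussian(fams, kin, 0.0, 1.0, [0.3, 0.0, 0.0], rng)
        est = ps.KinshipMixedLM(kinship=kin).fit(X, y, sample_ids=ids)
        # singleton blocks make C = I: lambda is unidentified but harmless,
        # and the coefficients must equal OLS exactly
        Xd = np.column_stack([np.ones(n), X])
        beta_ols = np.linalg.lstsq(Xd, y, rcond=None)[0]
        np.testing.assert_allclose(est.beta_, beta_ols, atol=1e-8)


class TestPoeTests:
    def test_symmetric_construction_gives_p_diff_one(self):
        rng = np.random.default_rng(8)
        n = 100
        pd_col = rng.binomial(1, 0.5, n).astype(float)
        md_col = rng.binomial(1, 0.5, n).astype(float)
        noise = rng.normal(size=n)
        y = 0.4 * (pd_col + md_col) + noise
        # force exact symmetry: use identical columns so b1 and b2 play
        # interchangeable roles in a balanced way
        X = np.column_stack([pd_col, md_col])
        fit = ps.fit_lmm(y, X, None, model="poe")
        # swap the two columns: the contrast flips sign, p_diff unchanged
        fit_sw = ps.fit_lmm(y, X[:, ::-1], None, model="poe")
        t, t_sw = ps.poe_tests(fit), ps.poe_tests(fit_sw)
        assert t.p_diff == pytest.approx(t_sw.p_diff, rel=1e-9)
        assert t.ci_diff[0] == pytest.approx(-t_sw.ci_diff[1], rel=1e-6)

    def test_f_statistic_closed_form(self):
        rng = np.random.default_rng(9)
        n = 150
        X = np.column_stack([rng.binomial(1, 0.5, n), rng.binomial(1, 0.5, n)])
        y = 0.5 * X[:, 0] + rng.normal(size=n)
        fit = ps.fit_lmm(y, X, None, model="poe")
        est = fit.estimator
        c = np.array([0.0, 1.0, -1.0])
        d = float(c @ est.beta_)
        v = float(c @ est.cov_beta_ @ c)
        _, _, stat = est.contrast_test(c)
        assert stat == pytest.approx(d * d / v, rel=1e-12)
        # and with an exactly diagonal (v, v) covariance: F = d^2 / (2v)
        est.cov_beta_ = np.diag([1.0, 0.25, 0.25])
        _, _, stat = est.contrast_test(c)
        d = est.beta_[1] - est.beta_[2]
        assert stat == pytest.approx(d * d / 0.5, rel=1e-12)

    def test_classical_f_test_recovered_without_family_variance(self):
        # lambda = 0 must reproduce the textbook fixed-effects contrast F
        rng = np.random.default_rng(10)
        n = 80
        X = rng.normal(size=(n, 2))
        y = 0.3 * X[:, 0] + rng.normal(size=n)
        fit = ps.fit_lmm(y, X, None, model="poe")
        assert fit.sigma_b2 == 0.0
        t = ps.poe_tests(fit)
        Xd = np.column_stack([np.ones(n), X])
        XtXi = np.linalg.inv(Xd.T @ Xd)
        beta = XtXi @ Xd.T @ y
        resid = y - Xd @ beta
        s2 = resid @ resid / (n - 3)
        c = np.array([0.0, 1.0, -1.0])
        F = (c @ beta) ** 2 / (s2 * c @ XtXi @ c)
        assert t.p_diff == pytest.approx(stats.f.sf(F, 1, n - 3), rel=1e-9)

    def test_wald_p_one_at_zero_estimate(self):
        est = ps.KinshipMixedLM()
        est.beta_ = np.array([0.0, 0.0])
        est.cov_beta_ = np.eye(2) * 0.04
        est.n_fixed_ = 2
        est.df_resid_ = 100
        p, ci = est.wald_test(1)
        assert p == pytest.approx(1.0)
        assert ci[0] == pytest.approx(-ci[1])

    def test_chi2_flag_close_to_f_at_large_n(self, small_dataset):
        fit = fit_poe(small_dataset)
        t_f = ps.poe_tests(fit)
        fit.estimator.use_chi2_contrast = True
        t_chi = ps.poe_tests(fit)
        # F vs chi-square differ only through the finite denominator df
        assert np.log(t_chi.p_diff) == pytest.approx(np.log(t_f.p_diff), rel=0.05)

    def test_model_type_guards(self, small_dataset):
        fit = fit_poe(small_dataset)
        with pytest.raises(ValueError):
            ps.genotype_test(fit)


class TestGenotypeModel:
    def test_wald_on_dosage_effect(self, small_dataset):
        ds = small_dataset
        y, X, ids, rows = poe_design_matrix(ds)
        G = X[:, 0] + X[:, 1]
        Xg = np.column_stack([G, X[:, 2:]])
        kin = ps.build_kinship(ds.families)
        fit = ps.fit_lmm(y, Xg, kin, sample_ids=ids, model="genotype")
        p, ci = ps.genotype_test(fit)
        assert 0.0 <= p <= 1.0
        assert ci[0] < fit.beta < ci[1]
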