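"""Twin SEM machinery: implied covariances, likelihood, fits, inference."""

import numpy as np
import pytest
from scipy import stats

import edutwin as et
from edutwin.synthetic import SimplexComponent, SimplexParams
from edutwin.twin_models import (
    FitError,
    FitResult,
    GroupCovariances,
    _cholesky_from_vector,
    _minimize_restarts,
    compare_models,
    falconer_estimates,
    fit_bivariate_cholesky,
    fit_cholesky,
    fit_common_pathway,
    fit_simplex,
    fit_univariate_ace,
    implied_covariance,
    innovation_share,
    intraclass_correlations,
    likelihood_ci,
    neg2ll,
    profile_interval,
    saturated_neg2ll,
    transmitted_share,
)

from conftest import exact_group_covariances, wishart_group_covariances


def identifiable_simplex_params():
    """A generating set in which every path is locally identified (nonzero
    E transmission and interior specifics), for noiseless-inversion checks."""
    return SimplexParams(
        a=SimplexComponent(0.8, (0.8, 0.7, 0.75), (0.35, 0.4, 0.3), (0.0, 0.15, 0.2, 0.0)),
        c=SimplexComponent(0.45, (0.85, 0.8, 0.9), (0.2, 0.25, 0.2), (0.0, 0.1, 0.1, 0.0)),
        e=SimplexComponent(0.3, (0.3, 0.25, 0.35), (0.3, 0.35, 0.3), (0.0, 0.12, 0.15, 0.0)),
    )


class TestIntraclassCorrelations:
    def test_identical_pairs_give_unity(self):
        t = et.simulate_ace(20, 20, et.ACEParams(1, 0, 0), seed=1)
        r = intraclass_correlations(t)
        assert r["MZ"] == pytest.approx(1.0)

    def test_independent_members_near_zero(self):
        t = et.simulate_ace(4000, 4000, et.ACEParams(0, 0, 1), seed=2)
        r = intraclass_correlations(t)
        assert abs(r["MZ"]) < 0.05

    def test_matches_brute_force_double_entry(self):
        # 10 hand-made MZ pairs; oracle: Pearson on the explicitly doubled vector
        import pandas as pd

        x1 = np.array([1.0, 2.0, 3.5, 2.2, 0.1, -1.0, 4.0, 2.8, 1.1, 0.0])
        x2 = np.array([1.2, 1.8, 3.0, 2.9, 0.4, -0.8, 3.1, 2.5, 0.7, 0.5])
        df = pd.DataFrame({
            "family_id": [f"f{i}" for i in range(10)] + [f"g{i}" for i in range(3)],
            "zygosity": ["MZ"] * 10 + ["DZ"] * 3,
            "sex1": "F", "sex2": "F",
            "ach1_1": np.r_[x1, [0.0, 1.0, 2.0]],
            "ach1_2": np.r_[x2, [0.5, 0.9, 1.8]],
        })
        table = et.TwinPairTable(data=df, n_occasions=1)
        doubled_a = np.r_[x1, x2]
        doubled_b = np.r_[x2, x1]
        mean_a, mean_b = doubled_a.mean(), doubled_b.mean()
        num = np.sum((doubled_a - mean_a) * (doubled_b - mean_b))
        den = np.sqrt(np.sum((doubled_a - mean_a) ** 2) * np.sum((doubled_b - mean_b) ** 2))
        assert intraclass_correlations(table)["MZ"] == pytest.approx(num / den, abs=1e-12)

    def test_too_few_pairs_names_group(self):
        t = et.simulate_ace(10, 2, et.ACEParams(0.6, 0.2, 0.2), seed=3)
        with pytest.raises(ValueError, match="DZ"):
            intraclass_correlations(t)


class TestFalconer:
    @pytest.mark.parametrize(
        "r_mz,r_dz,expected",
        [
            ((0.8), 0.5, (0.6, 0.2, 0.2)),
            (0.45, 0.45, (0.0, 0.45, 0.55)),
            (1.0, 0.5, (1.0, 0.0, 0.0)),
        ],
    )
    def test_formula(self, r_mz, r_dz, expected):
        f = falconer_estimates(r_mz, r_dz)
        assert (f.a2, f.c2, f.e2) == pytest.approx(expected)
        assert not f.out_of_bounds

    def test_out_of_bounds_flagged_not_clipped(self):
        f = falconer_estimates(0.4, 0.5)  # rDZ > rMZ -> negative A
        assert f.a2 == pytest.approx(-0.2)
        assert f.out_of_bounds


class TestImpliedCovariance:
    def test_univariate_ace_blocks(self):
        p = et.ACEParams(0.6, 0.2, 0.2)
        mz = implied_covariance("ace", p, "MZ")
        dz = implied_covariance("ace", p, "DZ")
        assert mz[0, 0] == pytest.approx(1.0)
        assert mz[0, 1] == pytest.approx(0.8)
        assert dz[0, 1] == pytest.approx(0.5)

    def test_simplex_without_paths_block_diagonal(self):
        comp = SimplexComponent(0.6, (0.0, 0.0), (0.5, 0.5), (0.0, 0.0, 0.0))
        params = SimplexParams(a=comp, c=comp, e=comp)
        sigma = implied_covariance("simplex", params, "MZ")
        within = sigma[:3, :3]
        assert np.allclose(within - np.diag(np.diag(within)), 0.0)

    def test_cpm_zero_residuals_rank_one(self, cpm_params):
        p = et.CommonPathwayParams(
            latent_a=cpm_params.latent_a, latent_c=cpm_params.latent_c,
            latent_e=cpm_params.latent_e, loadings=(0.9, 0.8, 0.7, 0.6),
            resid_a2=(0.0,) * 4, resid_c2=(0.0,) * 4, resid_e2=(0.0,) * 4,
        )
        sigma = implied_covariance("cpm", p, "MZ")
        assert np.linalg.matrix_rank(sigma[:4, :4], tol=1e-10) == 1

    def test_groups_differ_only_in_genetic_cross_block(self, simplex_params):
        mz = implied_covariance("simplex", simplex_params, "MZ")
        dz = implied_covariance("simplex", simplex_params, "DZ")
        t_n = simplex_params.n_occasions
        assert np.allclose(mz[:t_n, :t_n], dz[:t_n, :t_n])
        from edutwin.twin_models import _component_covs

        sig_a = _component_covs("simplex", simplex_params)[0]
        np.testing.assert_allclose(mz[:t_n, t_n:] - dz[:t_n, t_n:], 0.5 * sig_a)

    @pytest.mark.parametrize("model_params", [
        ("ace", et.ACEParams(0.5, 0.3, 0.2)),
        ("simplex", identifiable_simplex_params()),
    ])
    def test_symmetric_and_psd(self, model_params, cpm_params):
        model, params = model_params
        for zyg in ("MZ", "DZ"):
            sigma = implied_covariance(model, params, zyg)
            assert np.allclose(sigma, sigma.T)
            assert np.linalg.eigvalsh(sigma).min() > -1e-10


class TestNeg2ll:
    def _toy_data(self):
        rng = np.random.default_rng(7)
        covs = {}
        for g in ("MZ", "DZ"):
            a = rng.standard_normal((10, 2))
            covs[g] = np.cov(a, rowvar=False) + 0.5 * np.eye(2)
        return GroupCovariances(covs=covs, ns={"MZ": 10, "DZ": 10}, labels=["v1"])

    def test_saturation_identity(self):
        data = self._toy_data()
        value = neg2ll(dict(data.covs), data)
        assert value == pytest.approx(saturated_neg2ll(data), abs=1e-8)

    def test_any_perturbation_increases(self):
        data = self._toy_data()
        base = saturated_neg2ll(data)
        for g in ("MZ", "DZ"):
            for bump in (0.05, -0.05):
                sigmas = {k: v.copy() for k, v in data.covs.items()}
                sigmas[g] = sigmas[g] + bump * np.eye(2)
                assert neg2ll(sigmas, data) > base

    def test_matches_textbook_wishart_formula(self):
        # independently coded: -2lnL = sum_g n_g [p ln(2 pi) + ln det(Sigma) + tr(S Sigma^-1)]
        data = self._toy_data()
        sigmas = {g: s + 0.3 * np.eye(2) for g, s in data.covs.items()}
        expected = 0.0
        for g in ("MZ", "DZ"):
            s, sigma, n = data.covs[g], sigmas[g], data.ns[g]
            det = sigma[0, 0] * sigma[1, 1] - sigma[0, 1] * sigma[1, 0]
            inv = np.array([[sigma[1, 1], -sigma[0, 1]], [-sigma[1, 0], sigma[0, 0]]]) / det
            tr = sum(sum(s[i, k] * inv[k, i] for k in range(2)) for i in range(2))
            expected += n * (2 * np.log(2 * np.pi) + np.log(det) + tr)
        assert neg2ll(sigmas, data) == pytest.approx(expected, rel=1e-12)

    def test_nonpd_penalized_not_raised(self):
        data = self._toy_data()
        sigmas = {g: np.array([[1.0, 2.0], [2.0, 1.0]]) for g in ("MZ", "DZ")}
        assert neg2ll(sigmas, data) > 1e9


class TestUnivariateACE:
    def test_recovery_and_falconer_agreement(self, ace_cohort):
        # Monte-Carlo SD of each component estimate at 5000+5000 pairs is
        # ~0.018, so a 3-SD band is the sound single-replicate check here
        fit = fit_univariate_ace(ace_cohort, n_restarts=4)
        assert fit.derived["a2"] == pytest.approx(0.6, abs=0.06)
        assert fit.derived["c2"] == pytest.approx(0.2, abs=0.06)
        assert fit.derived["e2"] == pytest.approx(0.2, abs=0.03)
        fal = fit.derived["falconer"]
        assert fit.derived["a2"] == pytest.approx(fal["a2"], abs=0.04)

    def test_equal_twin_correlations_kill_heritability(self):
        data = exact_group_covariances("ace", et.ACEParams(0.0, 0.5, 0.5))
        fit = fit_univariate_ace(data, n_restarts=4)
        assert fit.derived["a2"] == pytest.approx(0.0, abs=1e-4)

    def test_noiseless_inversion(self):
        params = et.ACEParams(0.36, 0.33, 0.31)
        data = exact_group_covariances("ace", params)
        fit = fit_univariate_ace(data, n_restarts=3)
        assert fit.derived["a2"] == pytest.approx(0.36, abs=1e-5)
        assert fit.derived["c2"] == pytest.approx(0.33, abs=1e-5)
        assert fit.neg2ll == pytest.approx(saturated_neg2ll(data), abs=1e-6)

    def test_standardized_components_sum_to_one(self, ace_cohort):
        fit = fit_univariate_ace(ace_cohort, n_restarts=2)
        total = fit.derived["a2"] + fit.derived["c2"] + fit.derived["e2"]
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_falconer_and_ml_converge_at_large_n(self):
        data = wishart_group_covariances("ace", et.ACEParams(0.6, 0.2, 0.2), 50000, seed=21)
        fit = fit_univariate_ace(data, n_restarts=2)
        fal = fit.derived["falconer"]
        for key in ("a2", "c2", "e2"):
            assert fit.derived[key] == pytest.approx(fal[key], abs=0.02)


def bivariate_cholesky_params(h2=0.6, c2=0.2, r_g=0.8, r_c=0.9):
    """Cholesky generating values with genetic correlation r_g between two
    occasions, each with heritability h2 and shared environment c2."""
    def chol2(v, r):
        l11 = np.sqrt(v)
        l21 = r * np.sqrt(v)
        l22 = np.sqrt(v - l21**2)
        return np.array([[l11, 0.0], [l21, l22]])

    e2 = 1.0 - h2 - c2
    return et.CholeskyParams(
        l_a=chol2(h2, r_g), l_c=chol2(c2, r_c), l_e=chol2(e2, 0.2)
    )


class TestBivariateCholesky:
    def test_purely_genetic_covariance_share_one(self):
        params = et.CholeskyParams(
            l_a=np.array([[0.7, 0.0], [0.6, 0.3]]),
            l_c=np.diag([0.4, 0.4]),
            l_e=np.diag([0.5, 0.5]),
        )
        data = exact_group_covariances("cholesky", params)
        fit = fit_bivariate_cholesky(data, n_restarts=3)
        assert fit.derived["share_a"] == pytest.approx(1.0, abs=1e-4)

    def test_genetic_share_recovery_in_achievement_band(self):
        # generating share of the phenotypic correlation due to A: ~63-79%
        params = bivariate_cholesky_params()
        sig_a = params.l_a @ params.l_a.T
        sig_c = params.l_c @ params.l_c.T
        sig_e = params.l_e @ params.l_e.T
        true_share = sig_a[0, 1] / (sig_a + sig_c + sig_e)[0, 1]
        assert 0.63 < true_share < 0.79
        data = wishart_group_covariances("cholesky", params, 5000, seed=31)
        fit = fit_bivariate_cholesky(data, n_restarts=4)
        assert fit.derived["share_a"] == pytest.approx(true_share, abs=0.05)
        assert (
            fit.derived["share_a"] + fit.derived["share_c"] + fit.derived["share_e"]
            == pytest.approx(1.0, abs=1e-8)
        )

    def test_independent_measures_rg_ci_covers_zero(self):
        params = et.CholeskyParams(
            l_a=np.diag([0.77, 0.77]), l_c=np.diag([0.45, 0.45]), l_e=np.diag([0.45, 0.45])
        )
        data = wishart_group_covariances("cholesky", params, 2000, seed=32)
        fit = fit_bivariate_cholesky(data, n_restarts=2)
        lo, hi = likelihood_ci(fit, "la_21")
        assert lo <= 0.0 <= hi

    def test_near_zero_phenotypic_correlation_flagged(self):
        params = et.CholeskyParams(
            l_a=np.diag([0.77, 0.77]), l_c=np.diag([0.45, 0.45]), l_e=np.diag([0.45, 0.45])
        )
        data = exact_group_covariances("cholesky", params)
        fit = fit_bivariate_cholesky(data, n_restarts=2)
        assert np.isnan(fit.derived["share_a"])
        assert any("undefined" in f for f in fit.flags)


class TestSimplex:
    def test_noiseless_inversion(self):
        params = identifiable_simplex_params()
        data = exact_group_covariances("simplex", params)
        fit = fit_simplex(data, n_restarts=3)
        assert fit.neg2ll == pytest.approx(saturated_neg2ll(data), abs=1e-5)
        for got, want in zip(fit.derived["genetic_betas"], params.a.betas):
            assert got == pytest.approx(want, abs=1e-4)
        assert fit.estimates["a_init_sd"] == pytest.approx(params.a.init_sd, abs=1e-4)
        assert fit.estimates["e_innov_sd_3"] == pytest.approx(params.e.innov_sd[1], abs=1e-4)

    def test_no_cross_occasion_covariance_zero_betas(self):
        comp = SimplexComponent(0.6, (0.0, 0.0), (0.6, 0.6), (0.0, 0.0, 0.0))
        tiny = SimplexComponent(0.4, (0.0, 0.0), (0.4, 0.4), (0.0, 0.0, 0.0))
        params = SimplexParams(a=comp, c=tiny, e=tiny)
        data = exact_group_covariances("simplex", params)
        fit = fit_simplex(data, n_restarts=3)
        assert np.allclose(fit.derived["genetic_betas"], 0.0, atol=1e-3)

    def test_two_occasions_rejected(self):
        t = et.simulate_ace(300, 300, et.ACEParams(0.6, 0.2, 0.2), seed=4)
        with pytest.raises(ValueError, match="3 occasions"):
            fit_simplex(t)

    def test_too_few_pairs_rejected(self, simplex_params):
        t = et.simulate_simplex(60, 60, simplex_params, seed=5)
        with pytest.raises(ValueError, match="complete pairs|need >="):
            fit_simplex(t)


class TestShares:
    @pytest.mark.parametrize(
        "innov,spec,h2,expected",
        [
            (0.31, 0.0, 0.58, 0.31**2 / 0.58),  # ~17%: the GCSE innovation share
            (0.0, 0.0, 0.42, 0.0),
            (0.3, 0.0, 0.09, 1.0),
        ],
    )
    def test_innovation_share(self, innov, spec, h2, expected):
        assert innovation_share(innov, spec, h2) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "h2p,beta,h2c,expected",
        [
            (0.70, 0.84, 0.63, 0.70 * 0.84**2 / 0.63),  # ~78%
            (0.73, 0.86, 0.70, 0.73 * 0.86**2 / 0.70),  # ~77%
            (0.5, 0.0, 0.4, 0.0),
        ],
    )
    def test_transmitted_share(self, h2p, beta, h2c, expected):
        assert transmitted_share(h2p, beta, h2c) == pytest.approx(expected)

    def test_zero_heritability_rejected(self):
        with pytest.raises(ValueError):
            innovation_share(0.3, 0.0, 0.0)
        with pytest.raises(ValueError):
            transmitted_share(0.5, 0.8, 0.0)


class TestCommonPathway:
    def test_noiseless_inversion(self, cpm_params):
        data = exact_group_covariances("cpm", cpm_params)
        fit = fit_common_pathway(data, n_restarts=3)
        assert fit.neg2ll == pytest.approx(saturated_neg2ll(data), abs=1e-5)
        assert fit.derived["latent_a2"] == pytest.approx(0.70, abs=1e-4)
        assert fit.derived["latent_c2"] == pytest.approx(0.24, abs=1e-4)
        assert fit.derived["latent_e2"] == pytest.approx(0.06, abs=1e-4)
        np.testing.assert_allclose(fit.derived["loadings"], cpm_params.loadings, atol=1e-3)

    def test_nonshared_latent_factor_has_no_twin_covariance(self):
        p = et.CommonPathwayParams(
            latent_a=0.0, latent_c=0.0, latent_e=1.0, loadings=(0.9, 0.9, 0.9),
            resid_a2=(0.05,) * 3, resid_c2=(0.05,) * 3, resid_e2=(0.09,) * 3,
        )
        for zyg in ("MZ", "DZ"):
            sigma = implied_covariance("cpm", p, zyg)
            cross = sigma[:3, 3:]
            np.testing.assert_allclose(cross, np.diag(np.diag(cross)))
            assert np.all(np.diag(cross) < 0.11)

    def test_nested_in_cholesky(self, cpm_params):
        data = wishart_group_covariances("cpm", cpm_params, 2000, seed=41)
        cpm = fit_common_pathway(data, n_restarts=2)
        chol = fit_cholesky(data, n_restarts=2)
        assert cpm.neg2ll >= chol.neg2ll - 1e-3
        lrt, df, p = compare_models(chol, cpm)
        assert df == chol.n_free - cpm.n_free

    def test_standardized_components_sum_to_one(self, cpm_params):
        data = wishart_group_covariances("cpm", cpm_params, 3000, seed=42)
        fit = fit_common_pathway(data, n_restarts=2)
        total = np.asarray(fit.derived["a2"]) + fit.derived["c2"] + fit.derived["e2"]
        np.testing.assert_allclose(total, 1.0, atol=1e-6)
        assert (
            fit.derived["latent_a2"] + fit.derived["latent_c2"] + fit.derived["latent_e2"]
            == pytest.approx(1.0, abs=1e-10)
        )


class TestLikelihoodCI:
    def test_quadratic_toy_closed_form(self):
        crit = stats.chi2.ppf(0.95, 1)
        lo, hi, flags = profile_interval(lambda x: (x[0] - 1.0) ** 2, np.array([1.0]), 0, crit)
        assert lo == pytest.approx(1.0 - np.sqrt(crit), abs=1e-4)
        assert hi == pytest.approx(1.0 + np.sqrt(crit), abs=1e-4)
        assert not flags

    def test_interval_brackets_estimate(self, ace_cohort):
        fit = fit_univariate_ace(ace_cohort, n_restarts=2)
        lo, hi = likelihood_ci(fit, "a")
        assert lo < fit.estimates["a"] < hi
        assert hi - lo < 0.2  # well-conditioned at n=10000 pairs

    def test_null_coverage_of_a(self):
        # a2 = 0 truth; the interval for the 'a' path should cover 0 in ~95%
        # of replicates (conservative at the boundary)
        params = et.ACEParams(0.0, 0.4, 0.6)
        hits = 0
        n_rep = 120
        for rep in range(n_rep):
            data = wishart_group_covariances("ace", params, 300, seed=1000 + rep)
            try:
                fit = fit_univariate_ace(data, n_restarts=1)
                lo, hi = likelihood_ci(fit, "a")
            except FitError:
                continue
            if lo <= 0.0 <= hi + 1e-9:
                hits += 1
        assert hits / n_rep > 0.9


class TestCompareModels:
    def test_identical_models_null_result(self, ace_cohort):
        fit = fit_univariate_ace(ace_cohort, n_restarts=2)
        lrt, df, p = compare_models(fit, fit)
        assert lrt == 0.0 and df == 0 and p == 1.0

    def test_negative_lrt_raises(self):
        better = FitResult("m1", {}, neg2ll=100.0, n_free=3, converged=True, grad_norm=0)
        worse = FitResult("m0", {}, neg2ll=90.0, n_free=2, converged=True, grad_norm=0)
        with pytest.raises(FitError, match="optimization failure"):
            compare_models(better, worse)

    @staticmethod
    def _fit_cholesky_nested(data, fixed_zero=("la_21",), n_restarts=2, seed=0):
        """Bivariate Cholesky with selected paths constrained to zero."""
        full = fit_cholesky(data, n_restarts=n_restarts, seed=seed)
        labels = full._labels
        keep = [i for i, lab in enumerate(labels) if lab not in fixed_zero]

        def objective(x):
            full_x = np.zeros(len(labels))
            full_x[keep] = x
            return full._objective(full_x)

        x0 = full._x[keep]
        bounds = [full._bounds[i] for i in keep]
        best, converged, grad_norm, _ = _minimize_restarts(
            objective, [x0], bounds, scale=float(sum(data.ns.values()))
        )
        return full, FitResult(
            "cholesky_nested", dict(zip([labels[i] for i in keep], best.x)),
            neg2ll=float(best.fun), n_free=len(keep), converged=converged,
            grad_norm=grad_norm,
        )

    def test_null_calibration_dropping_zero_path(self):
        # la_21 = 0 in truth: LRT p-values should be roughly uniform
        params = et.CholeskyParams(
            l_a=np.diag([0.75, 0.75]),
            l_c=np.array([[0.45, 0.0], [0.40, 0.2]]),
            l_e=np.array([[0.48, 0.0], [0.1, 0.45]]),
        )
        pvals = []
        for rep in range(60):
            data = wishart_group_covariances("cholesky", params, 800, seed=2000 + rep)
            full, nested = self._fit_cholesky_nested(data, n_restarts=1, seed=rep)
            lrt, df, p = compare_models(full, nested)
            assert df == 1
            pvals.append(p)
        pvals = np.asarray(pvals)
        assert stats.kstest(pvals, "uniform").pvalue > 0.005
        assert 0.0 <= np.mean(pvals < 0.05) <= 0.15

    def test_power_dropping_real_genetic_path(self):
        params = bivariate_cholesky_params()
        data = wishart_group_covariances("cholesky", params, 2000, seed=51)
        full, nested = self._fit_cholesky_nested(data, n_restarts=2)
        lrt, df, p = compare_models(full, nested)
        assert p < 0.001


class TestRecoveryBias:
    """Mean parameter-recovery bias across replicates (scaled-down sizes)."""

    def test_simplex_beta_bias(self, simplex_params):
        reps = 8
        betas = np.zeros((reps, 3))
        for rep in range(reps):
            data = wishart_group_covariances("simplex", simplex_params, 10000, seed=3000 + rep)
            fit = fit_simplex(data, n_restarts=2, seed=rep)
            betas[rep] = fit.derived["genetic_betas_std"]
        bias = betas.mean(axis=0) - np.array([0.86, 0.84, 0.86])
        assert np.all(np.abs(bias) < 0.02)

    def test_cpm_latent_bias(self, cpm_params):
        reps = 8
        vals = np.zeros((reps, 3))
        for rep in range(reps):
            data = wishart_group_covariances("cpm", cpm_params, 10000, seed=4000 + rep)
            fit = fit_common_pathway(data, n_restarts=2, seed=rep)
            vals[rep] = [fit.derived["latent_a2"], fit.derived["latent_c2"],
                         fit.derived["latent_e2"]]
        bias = vals.mean(axis=0) - np.array([0.70, 0.24, 0.06])
        assert np.all(np.abs(bias) < 0.02)
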