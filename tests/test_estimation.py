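"""Likelihoods, quadrature, fitting and screening."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

import firecount as fc
from firecount import ModelSpec, ParamVector
from firecount._likelihood import build_matrices, linear_predictors, per_obs_loglik
from firecount.estimation import ParamPacker

from mc_oracle import mc_marginal_loglik


def _zip_spec():
    return ModelSpec("zip", "fixed", ("humidity", "wind_max"),
                     ("evaporation",), zero_intercept=True)


class TestConditionalLoglik:
    def test_term_by_term_oracle(self, tiny_panel):
        """Five hand-built ZIP terms summed independently with scipy."""
        spec = _zip_spec()
        pv = ParamVector(beta=[0.5, -0.01, 0.05], gamma=[-0.8, -0.01])
        got = fc.conditional_loglik(spec, pv, tiny_panel)
        expected = 0.0
        for _, row in tiny_panel.frame.iterrows():
            lam = np.exp(0.5 - 0.01 * row.humidity + 0.05 * row.wind_max)
            p = expit(-0.8 - 0.01 * row.evaporation)
            if row.fire_count == 0:
                expected += np.log(p + (1 - p) * np.exp(-lam))
            else:
                expected += (np.log1p(-p)
                             + stats.poisson.logpmf(row.fire_count, lam))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_hurdle_zero_contributes_log_p(self):
        df = pd.DataFrame({
            "county": ["a"], "year": [2000], "month": [1], "fire_count": [0],
            "tmax": [15.0], "tmean": [10.0], "humidity": [70.0],
            "wind_mean": [1.5], "wind_max": [5.0], "precipitation": [30.0],
            "evaporation": [50.0],
        })
        panel = fc.PanelDataset(df)
        spec = ModelSpec("hp", "fixed", ("wind_max",), ("evaporation",))
        pv = ParamVector(beta=[1.0, 0.1], gamma=[0.3, -0.02])
        p = expit(0.3 - 0.02 * 50.0)
        assert fc.conditional_loglik(spec, pv, panel) == pytest.approx(np.log(p))

    def test_u_zero_equals_fixed_likelihood(self, tiny_panel):
        spec = ModelSpec("nb", "mixed", ("wind_max",))
        pv = ParamVector(beta=[1.0, 0.05], theta=0.9, v1=0.3)
        fixed_pv = dataclasses.replace(pv, v1=0.0)
        assert fc.conditional_loglik(spec, pv, tiny_panel) == pytest.approx(
            fc.conditional_loglik(spec.fixed_version(), fixed_pv, tiny_panel)
        )

    def test_theta_domain_error(self, tiny_panel):
        spec = ModelSpec("nb", "fixed", ("wind_max",))
        with pytest.raises(ValueError, match="theta"):
            fc.conditional_loglik(
                spec, ParamVector(beta=[1.0, 0.0]), tiny_panel
            )


class TestAnalyticGradients:
    """The hand-derived score of every family matches finite differences."""

    @pytest.mark.parametrize("family", fc.FAMILIES)
    def test_fixed_effects_score(self, family, tiny_panel):
        two_part = family in ("zip", "zinb", "hp", "hnb")
        spec = ModelSpec(family, "fixed", ("humidity", "wind_max"),
                         ("evaporation",) if two_part else (),
                         zero_intercept=True)
        mat = build_matrices(spec, tiny_panel)
        packer = ParamPacker(spec)
        rng = np.random.default_rng(7)
        pv = ParamVector(
            beta=rng.normal(0, 0.2, 3) + [0.8, 0, 0],
            gamma=rng.normal(0, 0.02, 2) if two_part else None,
            theta=0.9 if spec.has_dispersion else None,
        )
        x = packer.pack(pv)

        def loglik(xv):
            pvx = packer.unpack(xv)
            eta, zeta = linear_predictors(mat, pvx)
            res = per_obs_loglik(family, mat.y, eta[:, None],
                                 None if zeta is None else zeta[:, None],
                                 pvx.theta)
            return float(res.ll.sum())

        res = per_obs_loglik(
            family, mat.y, (mat.Xc @ pv.beta)[:, None],
            (mat.Xz @ pv.gamma)[:, None] if two_part else None,
            pv.theta, want_du=True, want_da=spec.has_dispersion,
        )
        g = [mat.Xc.T @ res.du1[:, 0]]
        if two_part:
            g.append(mat.Xz.T @ res.dzeta[:, 0])
        if spec.has_dispersion:
            g.append(np.array([-(1.0 / pv.theta) * float(res.da.sum())]))
        analytic = np.concatenate(g)
        numeric = np.array([
            (loglik(x + h * e) - loglik(x - h * e)) / (2 * h)
            for i, e in enumerate(np.eye(x.size))
            for h in [1e-6 * max(1.0, abs(x[i]))]
        ])
        np.testing.assert_allclose(analytic, numeric, rtol=1e-5, atol=1e-6)


class TestMarginalLoglik:
    def test_degenerate_variance_equals_conditional(self, tiny_panel):
        spec = ModelSpec("poisson", "mixed", ("wind_max",))
        pv = ParamVector(beta=[0.8, 0.05], v1=0.0)
        marg = fc.marginal_loglik(spec, pv, tiny_panel)
        cond = fc.conditional_loglik(spec, pv, tiny_panel)
        assert marg == pytest.approx(cond, abs=1e-6)

    def test_variance_to_zero_limit(self, tiny_panel):
        spec = ModelSpec("poisson", "mixed", ("wind_max",))
        cond = fc.conditional_loglik(
            spec, ParamVector(beta=[0.8, 0.05], v1=0.0), tiny_panel
        )
        marg = fc.marginal_loglik(
            spec, ParamVector(beta=[0.8, 0.05], v1=1e-10), tiny_panel,
            quad_order=20,
        )
        assert marg == pytest.approx(cond, abs=1e-5)

    def test_quadrature_order_converged(self, tiny_panel):
        spec = ModelSpec("poisson", "mixed", ("wind_max",))
        pv = ParamVector(beta=[0.8, 0.05], v1=0.25)
        v20 = fc.marginal_loglik(spec, pv, tiny_panel, quad_order=20)
        v40 = fc.marginal_loglik(spec, pv, tiny_panel, quad_order=40)
        assert abs(v20 - v40) < 1e-6

    def test_against_monte_carlo_1d(self, tiny_panel):
        """2-cluster toy: order-30 quadrature vs 10^6-draw Monte Carlo."""
        spec = ModelSpec("poisson", "mixed", ("wind_max",))
        pv = ParamVector(beta=[0.8, 0.05], v1=0.25)
        quad = fc.marginal_loglik(spec, pv, tiny_panel, quad_order=30)
        mc, se = mc_marginal_loglik(spec, pv, tiny_panel, n_draws=10 ** 6)
        assert abs(quad - mc) < 3 * se

    def test_against_monte_carlo_2d(self, tiny_panel):
        spec = ModelSpec("zinb", "mixed", ("wind_max",), ("evaporation",),
                         zero_intercept=False)
        pv = ParamVector(beta=[1.0, 0.05], gamma=[-0.04], theta=0.8,
                         v1=0.2, v2=0.01)
        quad = fc.marginal_loglik(spec, pv, tiny_panel, quad_order=30)
        mc, se = mc_marginal_loglik(spec, pv, tiny_panel, n_draws=10 ** 6)
        assert abs(quad - mc) < 3 * se

    def test_adaptive_and_plain_agree_at_high_order(self, tiny_panel):
        spec = ModelSpec("nb", "mixed", ("wind_max",))
        pv = ParamVector(beta=[0.8, 0.05], theta=1.0, v1=0.2)
        ad = fc.marginal_loglik(spec, pv, tiny_panel, quad_order=25)
        plain = fc.marginal_loglik(spec, pv, tiny_panel, quad_order=60,
                                   adaptive=False)
        assert ad == pytest.approx(plain, abs=1e-5)


class TestFit:
    def test_intercept_only_poisson_closed_form(self, reference_panel):
        spec = ModelSpec("poisson", "fixed", ())
        res = fc.fit(spec, reference_panel)
        mle = res.estimates["count:intercept"]
        assert abs(mle - np.log(reference_panel.counts.mean())) < 1e-8

    def test_nb_fixed_parameter_recovery(self):
        """n=2000 simulated NB panel: estimates within 3 SEs of truth."""
        sc = fc.reference_scenarios()["nb-fixed"]
        sc = dataclasses.replace(sc, n_counties=20, n_years=25)  # 2000 rows
        panel = fc.generate_panel(sc, seed=11)
        res = fc.fit(sc.spec, panel, seed=0)
        assert res.converged and res.se_ok
        truth = dict(zip(
            ["count:intercept", "count:humidity", "count:wind_max",
             "count:evaporation"], sc.params.beta))
        truth["theta"] = sc.params.theta
        for name, tv in truth.items():
            z = abs(res.estimates[name] - tv) / res.se[name]
            assert z < 3.0, (name, z)

    def test_permutation_invariance(self, reference_panel):
        spec = ModelSpec("nb", "fixed", ("wind_max", "evaporation"))
        res1 = fc.fit(spec, reference_panel)
        shuffled = fc.PanelDataset(
            reference_panel.frame.sample(frac=1.0, random_state=5)
        )
        res2 = fc.fit(spec, shuffled)
        assert res2.loglik == pytest.approx(res1.loglik, abs=1e-6)
        for name in res1.names:
            assert res2.estimates[name] == pytest.approx(
                res1.estimates[name], abs=1e-5)

    def test_zip_nests_poisson(self):
        """On zero-inflated data the ZIP likelihood strictly dominates."""
        sc = fc.reference_scenarios()["zip-fixed"]
        panel = fc.generate_panel(sc, seed=2)
        covs = ("humidity", "wind_max", "evaporation")
        pois = fc.fit(ModelSpec("poisson", "fixed", covs), panel)
        zipf = fc.fit(ModelSpec("zip", "fixed", covs, ("evaporation",)), panel)
        assert zipf.loglik >= pois.loglik - 1e-3
        assert zipf.loglik > pois.loglik + 10  # clearly inflated data

    def test_mixed_fit_beats_fixed_on_clustered_data(self, nb_mixed_fit,
                                                     reference_panel):
        spec = nb_mixed_fit.spec.fixed_version()
        fixed = fc.fit(spec, reference_panel)
        assert nb_mixed_fit.loglik > fixed.loglik
        assert nb_mixed_fit.estimates["v1"] > 0.01

    def test_degenerate_data_rejected(self):
        df = pd.DataFrame({
            "county": ["a"] * 4, "year": 2000, "month": [1, 2, 3, 4],
            "fire_count": [2, 2, 2, 2],
            "tmax": 15.0, "tmean": 10.0, "humidity": 70.0, "wind_mean": 1.5,
            "wind_max": 5.0, "precipitation": 30.0, "evaporation": 50.0,
        })
        with pytest.raises(ValueError, match="distinct"):
            fc.fit(ModelSpec("poisson", "fixed", ()), fc.PanelDataset(df))


class TestStatsmodelsCrossCheck:
    """Independent implementations agree on the fixed-effects fits."""

    def test_poisson_and_nb(self, reference_panel):
        import statsmodels.api as sm
        covs = ("humidity", "wind_max", "evaporation")
        X = sm.add_constant(reference_panel.covariate_matrix(covs))
        y = reference_panel.counts
        ours = fc.fit(ModelSpec("poisson", "fixed", covs), reference_panel)
        sm_pois = sm.Poisson(y, X).fit(disp=0)
        assert ours.loglik == pytest.approx(sm_pois.llf, abs=1e-4)
        np.testing.assert_allclose(
            [ours.estimates[n] for n in ours.names],
            sm_pois.params, rtol=1e-4, atol=1e-6,
        )
        ours_nb = fc.fit(ModelSpec("nb", "fixed", covs), reference_panel)
        sm_nb = sm.NegativeBinomial(y, X).fit(disp=0, maxiter=200)
        assert ours_nb.loglik == pytest.approx(sm_nb.llf, abs=1e-3)
        assert ours_nb.estimates["theta"] == pytest.approx(
            sm_nb.params[-1], rel=1e-3)

    def test_zip(self, reference_panel):
        import statsmodels.api as sm
        covs = ("wind_max", "evaporation")
        X = sm.add_constant(reference_panel.covariate_matrix(covs))
        Xz = sm.add_constant(
            reference_panel.covariate_matrix(("evaporation",)))
        y = reference_panel.counts
        ours = fc.fit(
            ModelSpec("zip", "fixed", covs, ("evaporation",)), reference_panel
        )
        sm_zip = sm.ZeroInflatedPoisson(y, X, exog_infl=Xz).fit(
            disp=0, maxiter=500)
        assert ours.loglik == pytest.approx(sm_zip.llf, abs=1e-3)


class TestScreening:
    def _panel_with_noise(self, seed):
        sc = fc.reference_scenarios()["poisson-fixed"]
        sc = dataclasses.replace(sc, n_counties=10, n_years=10)
        return fc.generate_panel(sc, seed=seed)

    def test_informative_covariates_retained(self):
        panel = self._panel_with_noise(3)
        spec = ModelSpec("poisson", "fixed",
                         ("humidity", "wind_max", "evaporation"))
        sr = fc.screen_covariates(spec, panel)
        assert set(sr.spec.count_covariates) == {
            "humidity", "wind_max", "evaporation"}

    def test_alpha_one_removes_nothing(self):
        panel = self._panel_with_noise(4)
        spec = ModelSpec("poisson", "fixed",
                         ("humidity", "wind_max", "evaporation", "tmean"))
        sr = fc.screen_covariates(spec, panel, alpha=1.0)
        assert sr.spec.count_covariates == spec.count_covariates

    def test_noise_covariate_screened_out(self):
        """A covariate with no effect is dropped in >= 85% of 200 replicates
        (tmean is not in the generating model, so its true coefficient is
        only residually nonzero through its correlation with nothing)."""
        spec = ModelSpec("poisson", "fixed",
                         ("humidity", "wind_max", "evaporation", "tmean"))
        removed = 0
        n_rep = 200
        for rep in range(n_rep):
            panel = self._panel_with_noise(10_000 + rep)
            sr = fc.screen_covariates(spec, panel)
            if "count:tmean" in sr.removed:
                removed += 1
        assert removed / n_rep >= 0.85

    def test_mixed_zero_slope_protected(self):
        sc = fc.reference_scenarios()["zinb-mixed"]
        panel = fc.generate_panel(sc, seed=9)
        sr = fc.screen_covariates(sc.spec, panel, alpha=1e-9)
        assert "evaporation" in sr.spec.zero_covariates
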