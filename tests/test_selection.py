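"""AIC/BIC, the printed criterion contrasts, and the d_j diagnostic."""

import dataclasses

import numpy as np
import pytest

import firecount as fc
from firecount import ModelSpec, ParamVector, aic, bic, relative_criterion_increase
from firecount.selection import dj_from_probabilities

from mc_oracle import mc_marginal_loglik  # noqa: F401  (imported for parity)


class TestCriteria:
    def test_aic_closed_forms(self):
        assert aic(0.0, 0) == 0.0
        assert aic(-1802.7, 4) == pytest.approx(3613.4)
        assert aic(-100.0, 5) - aic(-100.0, 4) == pytest.approx(2.0)

    def test_bic_closed_forms(self):
        assert bic(-7.5, 3, 1) == pytest.approx(15.0)    # penalty vanishes
        assert bic(-1802.7, 4, 435) == pytest.approx(3629.7, abs=0.05)
        # BIC >= AIC once n >= 8 (ln n >= 2)
        assert bic(-10.0, 2, 8) >= aic(-10.0, 2)

    def test_relative_increase(self):
        assert relative_criterion_increase(150.0, 100.0) == pytest.approx(50.0)
        assert relative_criterion_increase(42.0, 42.0) == 0.0
        with pytest.raises(ValueError):
            relative_criterion_increase(1.0, 0.0)

    def test_mixed_bic_uses_cluster_count(self, nb_mixed_fit):
        auto = nb_mixed_fit.bic()
        assert auto == pytest.approx(nb_mixed_fit.bic("clusters"))
        assert nb_mixed_fit.bic("obs") > auto   # ln 576 > ln 12


class TestDjTable:
    def test_saturated_predictor_gives_zero(self):
        """A predictor equal to the empirical distribution has d_j = 0."""
        y = np.array([0, 0, 1, 2, 2, 2, 5])
        emp = np.bincount(y, minlength=8) / y.size
        probs = np.tile(emp, (y.size, 1))
        diag = dj_from_probabilities(probs, y)
        np.testing.assert_allclose(diag.d, 0.0, atol=1e-15)

    def test_dj_sums_telescope_to_zero(self, nb_mixed_fit, reference_panel):
        """Sum_j d_j equals mean P(y_i <= J) - 1 = -tail mass exactly, and
        shrinks toward zero as the class range J grows."""
        small = fc.dj_table(nb_mixed_fit, reference_panel,
                            max_class=int(reference_panel.counts.max()))
        big = fc.dj_table(nb_mixed_fit, reference_panel,
                          max_class=int(reference_panel.counts.max()) + 60)
        assert small.d.sum() == pytest.approx(-small.tail_mass, abs=1e-10)
        assert big.d.sum() == pytest.approx(-big.tail_mass, abs=1e-10)
        assert abs(big.d.sum()) < abs(small.d.sum())
        assert abs(big.d.sum()) < 1e-3

    def test_observed_proportions_sum_to_one(self, nb_mixed_fit,
                                             reference_panel):
        diag = fc.dj_table(nb_mixed_fit, reference_panel)
        assert diag.table["observed_prop"].sum() == pytest.approx(1.0)

    def test_poisson_underestimates_zero_class_on_inflated_data(self):
        """The qualitative diagnostic signature: fitting a Poisson to
        strongly zero-inflated counts yields d_0 < 0."""
        sc = fc.reference_scenarios()["zip-fixed"]
        pv = dataclasses.replace(sc.params, gamma=np.array([1.0, -0.01]))
        sc = dataclasses.replace(sc, params=pv)     # ~60% structural zeros
        panel = fc.generate_panel(sc, seed=21)
        res = fc.fit(
            ModelSpec("poisson", "fixed", sc.spec.count_covariates), panel
        )
        diag = fc.dj_table(res, panel)
        assert diag.d[0] < -0.05

    def test_mixed_marginal_probabilities_match_monte_carlo(self, tiny_panel):
        """Random-effect marginalization in dj_table agrees with brute-force
        averaging over 10^5 Gaussian draws."""
        spec = ModelSpec("nb", "mixed", ("wind_max",))
        pv = ParamVector(beta=[0.9, 0.05], theta=0.8, v1=0.3)
        res = fc.fit(spec, tiny_panel, seed=0)
        probs = fc.predicted_probabilities(res, tiny_panel, max_class=10)
        rng = np.random.default_rng(0)
        n_draws = 10 ** 5
        u = rng.normal(0, np.sqrt(res.params.v1), n_draws)
        from scipy import stats as ss
        mat_lam = np.exp(
            res.params.beta[0]
            + tiny_panel.covariate_matrix(("wind_max",))[:, 0:1]
            * res.params.beta[1] + u[None, :]
        )
        a = 1.0 / res.params.theta
        for j in (0, 1, 3):
            mc = ss.nbinom.pmf(j, a, a / (a + mat_lam)).mean(axis=1)
            se = ss.nbinom.pmf(j, a, a / (a + mat_lam)).std(axis=1) / np.sqrt(n_draws)
            assert np.all(np.abs(probs[:, j] - mc) < 3 * se + 1e-4)

    def test_unconverged_fit_rejected(self, nb_mixed_fit, reference_panel):
        bad = dataclasses.replace(nb_mixed_fit, converged=False)
        with pytest.raises(ValueError, match="converged"):
            fc.dj_table(bad, reference_panel)


class TestCompareModels:
    def test_single_fit_flagged_best(self, nb_mixed_fit):
        table = fc.compare_models([nb_mixed_fit])
        assert len(table) == 1
        assert bool(table.loc[0, "best_aic"]) and bool(table.loc[0, "best_bic"])

    def test_sorted_by_aic(self, nb_mixed_fit, reference_panel):
        fixed = fc.fit(nb_mixed_fit.spec.fixed_version(), reference_panel)
        pois = fc.fit(
            ModelSpec("poisson", "fixed", ("wind_max", "evaporation")),
            reference_panel,
        )
        table = fc.compare_models([pois, fixed, nb_mixed_fit])
        assert list(table["aic"]) == sorted(table["aic"])
        assert table.loc[0, "model"] == "nb-mixed"

    def test_mixed_datasets_refused(self, nb_mixed_fit):
        sc = fc.reference_scenarios()["nb-mixed"]
        other = fc.generate_panel(sc, seed=99)
        other_fit = fc.fit(sc.spec.fixed_version(), other)
        with pytest.raises(ValueError, match="different datasets"):
            fc.compare_models([nb_mixed_fit, other_fit])
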