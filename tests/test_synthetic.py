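"""Synthetic panel generator: determinism, moments, count laws, presets."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import firecount as fc
from firecount import ModelSpec, ParamVector
from firecount.synthetic import (
    DEFAULT_COVARIATE_MOMENTS,
    ScenarioConfig,
    generate_covariates,
    simulate_counts,
)


def _intercept_only_scenario(family, beta0, gamma0=None, theta=None,
                             n_counties=10, n_years=25):
    spec = ModelSpec(
        family, "fixed", (),
        zero_covariates=() if family in ("poisson", "nb") else (),
        zero_intercept=family not in ("poisson", "nb"),
    )
    params = ParamVector(
        beta=[beta0],
        gamma=None if gamma0 is None else [gamma0],
        theta=theta,
    )
    return ScenarioConfig(name="toy", spec=spec, params=params,
                          n_counties=n_counties, n_years=n_years)


class TestCovariates:
    def test_deterministic_given_seed(self):
        sc = fc.reference_scenarios()["nb-mixed"]
        a = generate_covariates(sc, seed=7).frame
        b = generate_covariates(sc, seed=7).frame
        pd.testing.assert_frame_equal(a, b)

    def test_reference_dimensions(self):
        sc = fc.reference_scenarios()["nb-mixed"]
        panel = generate_covariates(sc, seed=0)
        assert panel.n_obs == 576            # 12 counties x 12 years x 4 months
        assert panel.n_clusters == 12
        assert sorted(panel.frame["month"].unique()) == [1, 2, 3, 4]

    def test_draws_respect_configured_bounds(self):
        sc = fc.reference_scenarios()["nb-mixed"]
        panel = generate_covariates(sc, seed=1)
        for cov, m in DEFAULT_COVARIATE_MOMENTS.items():
            vals = panel.frame[cov]
            assert vals.min() >= m.min and vals.max() <= m.max, cov

    def test_inconsistent_mean_warns(self):
        sc = fc.reference_scenarios()["nb-mixed"]
        with pytest.warns(UserWarning, match="tmax"):
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("always")
                generate_covariates(sc, seed=2)


class TestCounts:
    def test_poisson_mean_lln(self):
        sc = _intercept_only_scenario("poisson", np.log(3.0))
        panel = fc.generate_panel(sc, seed=3)      # 1000 rows
        n = panel.n_obs
        se = np.sqrt(3.0 / n)
        assert abs(panel.counts.mean() - 3.0) < 3 * se

    def test_nb_variance_formula(self):
        # lam=2, theta=1 -> variance lam + theta lam^2 = 6
        sc = _intercept_only_scenario("nb", np.log(2.0), theta=1.0,
                                      n_counties=20, n_years=125)
        panel = fc.generate_panel(sc, seed=4)      # 10^4 rows
        var = panel.counts.var(ddof=1)
        # var of the sample variance of an overdispersed count ~ heavy; allow 4 SE
        assert var == pytest.approx(6.0, rel=0.15)

    def test_zip_zero_fraction(self):
        # p=0.5, lam=5 -> P(0) = 0.5 + 0.5 e^-5
        sc = _intercept_only_scenario("zip", np.log(5.0), gamma0=0.0)
        panel = fc.generate_panel(sc, seed=5)
        p0 = 0.5 + 0.5 * np.exp(-5.0)
        n = panel.n_obs
        se = np.sqrt(p0 * (1 - p0) / n)
        assert abs((panel.counts == 0).mean() - p0) < 3 * se

    def test_hurdle_positive_counts_truncated(self):
        sc = _intercept_only_scenario("hp", np.log(0.3), gamma0=-1.0)
        panel = fc.generate_panel(sc, seed=6)
        y = panel.counts
        p = 1.0 / (1.0 + np.exp(1.0))
        se = np.sqrt(p * (1 - p) / y.size)
        assert abs((y == 0).mean() - p) < 3 * se
        # positive part is truncated Poisson: mean lam / (1 - e^-lam)
        lam = 0.3
        m_pos = lam / (1 - np.exp(-lam))
        assert y[y > 0].mean() == pytest.approx(m_pos, rel=0.05)

    def test_mixed_counts_cluster_heterogeneity(self):
        sc = fc.reference_scenarios()["nb-mixed"]
        panel = fc.generate_panel(sc, seed=7)
        cluster_means = panel.frame.groupby("county")["fire_count"].mean()
        # v1 = 0.23 on the log scale spreads county means well beyond
        # Poisson-like noise
        assert cluster_means.max() / max(cluster_means.min(), 0.1) > 1.5


class TestReferenceScenarios:
    def test_twelve_presets(self):
        scenarios = fc.reference_scenarios()
        assert len(scenarios) == 12
        assert {s.split("-")[1] for s in scenarios} == {"fixed", "mixed"}
        assert {s.split("-")[0] for s in scenarios} == set(fc.FAMILIES)

    def test_nb_mixed_generating_values(self):
        sc = fc.reference_scenarios()["nb-mixed"]
        assert sc.params.theta == pytest.approx(0.99)
        assert sc.params.v1 == pytest.approx(0.23)
        assert sc.spec.count_covariates == ("wind_max", "evaporation")

    def test_all_presets_valid_paramvectors(self):
        for name, sc in fc.reference_scenarios().items():
            assert sc.params.v1 >= 0 and sc.params.v2 >= 0, name
            assert sc.n_rows == 576, name
            k = sc.spec.n_params()
            assert k >= 2, name

    def test_inflated_scale(self):
        sc = fc.inflated_scenario("zinb-mixed")
        assert sc.n_counties == 50
        assert sc.n_rows == 50 * 100
        base = fc.reference_scenarios()["zinb-mixed"]
        assert np.allclose(sc.params.beta, base.params.beta)

    def test_zero_inflation_raises_zero_fraction(self):
        """ZI presets produce more zeros than their base-family counterpart
        at identical count parameters."""
        zip_sc = fc.reference_scenarios()["zip-fixed"]
        base_spec = ModelSpec("poisson", "fixed", zip_sc.spec.count_covariates)
        base_params = ParamVector(beta=zip_sc.params.beta)
        skel = generate_covariates(zip_sc, seed=8)
        zi = simulate_counts(skel, zip_sc.spec, zip_sc.params, seed=9)
        po = simulate_counts(skel, base_spec, base_params, seed=9)
        assert (zi.counts == 0).mean() > (po.counts == 0).mean()


def test_generate_panel_determinism():
    sc = fc.reference_scenarios()["hnb-mixed"]
    a = fc.generate_panel(sc, seed=13)
    b = fc.generate_panel(sc, seed=13)
    pd.testing.assert_frame_equal(a.frame, b.frame)
    c = fc.generate_panel(sc, seed=14)
    assert not a.frame["fire_count"].equals(c.frame["fire_count"])
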