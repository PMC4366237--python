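# firecount

Count-data regression for monthly fire-occurrence panels: six model
families — Poisson, negative binomial (NB), zero-inflated Poisson/NB
(ZIP/ZINB) and hurdle Poisson/NB (HP/HNB) — each with or without
county-level Gaussian random effects, fitted by maximum likelihood with
adaptive Gauss–Hermite quadrature, compared by AIC/BIC, and diagnosed with
per-count-class fitted-vs-observed probability differences.

## Who this is for

Forest-fire occurrence counts (and monthly event counts generally) are
overdispersed and zero-heavy: many county-months record no fires at all,
while a few record dozens. `firecount` is for analysts who want to model a
panel of such counts against meteorological covariates — monthly maximum and
mean temperature, relative humidity, mean and maximum wind speed,
precipitation, evaporation — while accounting for unexplained county-to-
county variability with random effects, and then ask *which* count
distribution the data actually support.

## The models

For observation $i$ in county $k$ with covariates $x_i$, the count mean
follows a log link

$$\lambda_i = \exp(x_i^\top \beta + u_{1k}), \qquad u_{1k} \sim N(0, v_1),$$

with the base count law either Poisson($\lambda$) or NB($\lambda, \theta$)
with variance $\lambda + \theta\lambda^2$. The two-part families add a
logistic zero model

$$p_i = \operatorname{logit}^{-1}(x_{0i}^\top \gamma + u_{2k} E_i), \qquad
u_{2k} \sim N(0, v_2),$$

where the random slope $u_2$ acts on evaporation $E$. Zero-inflated
families mix a point mass at zero with the full count law
($P(0) = p + (1-p)f(0)$); hurdle families use a Bernoulli zero process with
a truncated-at-zero count law for the positives. Mixed-model likelihoods
integrate $(u_1, u_2)$ out by adaptive Gauss–Hermite quadrature. Fit is
compared by $\mathrm{AIC} = -2\ell + 2k$ and
$\mathrm{BIC} = -2\ell + k\ln n$ (with $n$ = clusters for mixed models, the
convention consistent with the reference analysis), and per count class $j$

$$d_j = \frac{1}{n}\sum_i P(y_i = j \mid \text{fit}) - \frac{\#\{y_i = j\}}{n},$$

so $d_0 \ll 0$ flags a model that cannot produce enough zeros.

Because the original fire/weather panel was never deposited, the package
ships a synthetic generator (`firecount.synthetic`) whose presets reproduce
the published covariate summaries and use the published point estimates of
all twelve models as generating values.

## Worked example

```python
import firecount as fc

scenario = fc.reference_scenarios()["nb-mixed"]   # NB + county intercepts
panel = fc.generate_panel(scenario, seed=1)       # 12 counties x 12 years x 4 months
result = fc.fit(scenario.spec, panel, seed=0)
print(result)
print(result.to_frame().round(4).to_string(index=False))
```

prints

```
<FitResult nb-mixed: loglik=-1653.291 k=5 AIC=3316.6 converged=True>
        parameter  estimate     se       t      p sig
  count:intercept    1.6340 0.2578  6.3385 0.0000  **
   count:wind_max    0.0695 0.0246  2.8307 0.0046  **
count:evaporation   -0.0047 0.0019 -2.4113 0.0159  **
            theta    0.9584 0.0708 13.5429 0.0000  **
               v1    0.3201 0.1410  2.2703 0.0232  **
```

The generating values were intercept 1.42, wind 0.09, evaporation −0.005,
θ = 0.99, v₁ = 0.23: every estimate sits within sampling error at this
panel size. θ near 1 confirms strong overdispersion (variance ≈ λ + λ²) and
v₁ > 0 confirms county heterogeneity beyond the covariates. Examples
`examples/01...05` walk through simulation, single fits, the twelve-model
AIC/BIC comparison, the d_j diagnostic, and the one-command study pipeline;
a thin CLI (`firecount simulate/fit/compare/diagnose/run`) wraps the same
calls for shell use.

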