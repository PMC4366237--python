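# Methods

This note documents the statistical models, numerical methods, and design
choices behind `firecount`, in the spirit of a model-documentation page:
what is computed, under which assumptions, with which defaults, and where
the edges are.

## Models

Let $y_{ik}$ be the fire count of observation $i$ in county $k$, with count
covariates $x_i$ and zero-model covariates $x_{0i}$.

**Base count laws.** Poisson($\lambda$) with
$\log\lambda_i = x_i^\top\beta + u_{1k}$, or negative binomial NB2 with the
same log link, mean $\lambda$ and variance $\lambda + \theta\lambda^2$. The
dispersion convention is the "$\theta\lambda^2$" one: software parameterized
by a size $r$ corresponds to $r = 1/\theta$, and $\theta \to 0$ recovers the
Poisson.

**Two-part families.** Zero-inflated (ZIP/ZINB): $P(0) = p + (1-p)f(0)$,
$P(y) = (1-p)f(y)$ for $y > 0$. Hurdle (HP/HNB): $P(0) = p$,
$P(y) = (1-p)f(y)/(1-f(0))$ for $y > 0$. Both use a logistic zero model
$\operatorname{logit} p_i = x_{0i}^\top\gamma + u_{2k}E_i$, where the random
slope $u_2$ multiplies evaporation (configurable via
`ModelSpec.zero_random_slope`). The two parameterizations describe the same
distribution when $p_{\text{hurdle}} = p_{\text{zi}} + (1-p_{\text{zi}})f(0)$;
a property test asserts that identity.

**Random effects.** $u_1 \sim N(0, v_1)$ on the count intercept;
two-part mixed models add $u_2 \sim N(0, v_2)$ on the zero-model slope. The
covariance of $(u_1, u_2)$ is diagonal by default — matching the published
variance table, which reports no covariance — with an unstructured option
(`re_structure="unstructured"`) since the source text mentions an
unstructured structure. The unstructured path is fitted with numerically
differentiated gradients and is slower.

Zero-model intercepts are a per-spec flag: the reference parameterization
has one for ZIP/HP and none for ZINB/HNB; both shapes are expressible and
the pipeline applies that convention by default. Whether the missing
NB-based zero intercepts reflect screening or a deliberate no-intercept
model is not stated in the source; the presets simply reproduce the
published shape.

## Likelihood evaluation

All probability mass functions are evaluated on the log scale with
log-gamma, `log1p`/`expm1` and log-sum-exp; linear predictors are clipped at
±40 (beyond which the log-likelihood is astronomically negative anyway, and
unclipped values stall vector arithmetic on denormals). The NB log-pmf
switches to an exact rising-factorial form when $1/\theta > 10^6$, where the
log-gamma difference loses half its digits; this makes the $\theta \to 0$
Poisson limit numerically clean.

**Marginal likelihood.** For mixed models the cluster likelihood is
integrated over the random effects by adaptive Gauss–Hermite quadrature:
per cluster, a damped Newton search (batched across clusters, analytic
gradients, finite-difference curvature) locates the posterior mode of
$(u_1, u_2)$; the Gauss–Hermite grid is centred and scaled there (tensor
grid in two dimensions, with the count-side quantities evaluated on the few
unique $u_1$ nodes and expanded); cluster integrals are accumulated by
log-sum-exp. Degenerate variances drop the corresponding integration
dimension, so $v_1 = v_2 = 0$ reduces exactly to the conditional likelihood
at $u = 0$.

## Fitting

Fixed-effects models: BFGS with analytic score ($\theta$ on the log scale),
started from the closed form $\beta_0 = \log \bar y$, other coefficients 0,
$\gamma = 0$, $\theta = 1$. The intercept-only Poisson start is already the
MLE, which the suite checks to $10^{-8}$.

Mixed models are warm-started from their fixed twin with starting variances
0.05, and maximized by a **freeze/re-adapt scheme**: the quadrature rule is
adapted at the current estimate and then frozen; under a frozen rule the
score from Fisher's identity (posterior-weighted conditional score, plus
the Gaussian-prior score for the log-variances) is the *exact* gradient of
the approximated marginal likelihood, so the inner maximization is fast and
clean; the rule is then re-adapted and the cycle repeats. The first cycle
uses BFGS; later cycles take Newton steps reusing one finite-difference
Hessian. Variances and $\theta$ are optimized as logs; design columns are
internally scaled to unit RMS (scale only, never centred — a no-intercept
zero model must not acquire a hidden constant) and estimates are mapped
back exactly.

**Fixed-point behaviour.** The map "estimate → argmax under the rule
adapted there" contracts when the cluster posteriors are close to Gaussian.
When a zero-slope posterior is strongly skewed (a cluster whose observed
zero pattern pins $u_2$ against a soft wall), low-order rules can cycle
instead of contracting. Two mechanisms handle this:

* the iteration is declared settled when the re-adaptation update is either
  below an absolute tolerance or below a quarter of every parameter's
  standard error — rule ambiguity below that level has no inferential
  consequence and is reported honestly via `gradient_norm` and `message`;
* otherwise the quadrature order is escalated (default ladder 9 → 13 → 17
  nodes per dimension) until the map contracts; the order actually used is
  recorded on the result.

A final polish solve makes the reported estimate an exact stationary point
of its own self-adapted rule. The default order of 9 nodes per dimension is
both an accuracy and a *stability* floor: below it the two-part families'
fixed point stops contracting. At the reference scales, moving from order 9
to order 31 shifts every estimate by at most ~0.2 standard errors (checked
with accurate-gradient Newton shifts).

Standard errors come from the observed information of the rule frozen at
the optimum (finite differences of the analytic score), with the delta
method mapping log-scale parameters back; Wald $t$-statistics use a normal
reference — the source says only "T-test", so the normal reference is a
documented convention. Convergence is never silently assumed: the result
carries an honest `converged` flag, the gradient norm, and a nesting sanity
check (a mixed fit whose likelihood falls below its fixed-effects start is
flagged). Up to three jittered restarts run before a failure is reported.

## Screening, selection, diagnostics

`screen_covariates` fits the full model once and removes *all* covariates
with Wald $p > \alpha$ (default 0.1) at once — the source does not state a
stepwise order, so single-pass removal is the documented choice. Intercepts
are never screened; in a two-part mixed spec the covariate carrying the
zero-model random slope is retained regardless, because removing it would
remove the random effect itself. The pipeline screens per family on the
fixed-effects model and reuses the reduced covariate sets for the mixed twin.

AIC $= -2\ell + 2k$; BIC $= -2\ell + k\ln n$ with $n$ = observations for
fixed models and $n$ = clusters for mixed models by default. The cluster
convention is the only one consistent with the published AIC–BIC gaps
(e.g. a mixed-Poisson gap of 2.4 ≈ $5(\ln 12 - 2)$); both conventions are
selectable.

The $d_j$ diagnostic averages fitted class probabilities over observations
and subtracts observed class proportions. In the source's notation the
normalizer is described as the number of count classes, but both terms are
proportions only if it is the number of observations, which is what is
implemented. For mixed fits the probabilities marginalize over the random
effects by prior-centred Gauss–Hermite quadrature (order 30) — a single
observation barely narrows the posterior, so prior-centred nodes suffice;
whether the original figures used conditional or marginal probabilities is
unstated, and marginal is the default. The identity
$\sum_j d_j = -(\text{mean predicted tail mass beyond } J)$ holds exactly
and is tested. `max_class` defaults to the largest observed count plus 5,
with the remaining tail mass reported.

## Synthetic data

The generator emulates a 12-county × 12-year × 4-month (January–April)
panel. Covariates are truncated normals matching published per-covariate
(min, max, mean, SD) summaries — only those four numbers are published, so
any distribution matching them is admissible and the choice is documented
rather than unique — with seeded additive county and month shifts (SD = 20%
of the covariate SD each, residual SD shrunk to preserve the total) to
induce within-panel structure. Covariates are drawn independently of each
other; real weather covariates are cross-correlated, so passing tests say
nothing about collinearity behaviour on real data. One published summary row
(maximum temperature) has a mean above its maximum; the generator targets
the printed values as-is, warns, and lets the truncation dominate. The exact
moment targets are therefore *analytic truncated-normal* expectations, which
is what the moment tests compare against.

Counts are drawn from the exact generating law: gamma-mixed Poisson for NB;
indicator-then-count for zero-inflated; indicator-then-truncated-count for
hurdle, with the truncated draw by exact inverse CDF
($y = F^{-1}(f_0 + U(1-f_0))$). Mixed presets draw $(u_1, u_2)$ once per
county.

Twelve presets use the published point estimates of each fitted model as
generating values, including each column's covariate set and zero-intercept
shape. One published value, the ZIP-mixed $v_2 = -0.008$, is impossible as
a variance; the preset uses its magnitude. The published panel size is
ambiguous (a complete panel would be 576 rows; the fixed-model AIC–BIC gaps
imply roughly 435 usable rows), so presets expose the panel shape as
parameters with the complete 576-row panel as default. An `inflated_scenario`
variant (50 counties × 25 years, i.e. 100 rows per cluster) supports
parameter-recovery studies; recovery tests run 20 seeded replicates per
preset, warm-starting replicates after the first from the first fit — a
Monte-Carlo convenience; the first replicate exercises the default
initialization.

## Problem sizes used by the test-suite and acceptance script

Quadrature-vs-Monte-Carlo checks use 2-cluster toy panels with $10^6$
prior draws (batched standard errors, since the importance weights are
heavy-tailed). Recovery runs 12 presets × 20 replicates at the 50-cluster
scale; the two-part mixed presets are fitted with 13 quadrature nodes per
dimension there, which keeps the numerical noise of the estimates well
below their standard errors (at order 9 the residual rule ambiguity is a
non-trivial fraction of the zero-slope SE). Model-selection consistency runs 10 replicates of the full
twelve-model comparison at the 576-row reference scale (the scaled-down
version of the 50-replicate design). The acceptance script fits one
inflated-scale NB-mixed panel, six selection replicates, and one
misspecified-Poisson diagnostic panel.

## Known limitations

* The real fire/weather panel was never deposited; all numerical claims are
  about the synthetic study conditions, not the original data.
* Low-order adaptive quadrature leaves a small rule ambiguity (≤ 0.25 SE by
  construction) for two-part mixed fits on small panels; order escalation
  bounds it but cannot remove the underlying skewness of zero-slope
  posteriors.
* The unstructured random-effects covariance path uses numeric gradients
  and is substantially slower; the diagonal default matches the published
  analysis.
* No spatial or temporal autocorrelation, offsets, interactions or splines;
  main effects only, as in the reference analysis.
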