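"""Brute-force Monte-Carlo oracle for the random-effects marginal likelihood.

Deliberately independent of the package's likelihood code: per-observation
probabilities come from scipy.stats and explicit mixture formulas, and the
random effects are integrated by plain Monte Carlo over Gaussian draws.
"""

import numpy as np
from scipy import stats
from scipy.special import expit, logsumexp


def mc_marginal_loglik(spec, params, panel, n_draws=10 ** 6, seed=0):
    """Return (log-likelihood estimate, Monte-Carlo standard error)."""
    rng = np.random.default_rng(seed)
    df = panel.frame
    total, var = 0.0, 0.0
    for county, idx in panel.clusters.items():
        sub = df.iloc[idx]
        y = sub["fire_count"].to_numpy()
        Xc = sub[list(spec.count_covariates)].to_numpy()
        eta0 = params.beta[0] + Xc @ params.beta[1:]
        u1 = (rng.normal(0.0, np.sqrt(params.v1), n_draws)
              if params.v1 > 0 else np.zeros(n_draws))
        lam = np.exp(eta0[:, None] + u1[None, :])
        if spec.family in ("poisson", "zip", "hp"):
            base = stats.poisson.logpmf(y[:, None], lam)
            logf0 = stats.poisson.logpmf(0, lam)
        else:
            a = 1.0 / params.theta
            base = stats.nbinom.logpmf(y[:, None], a, a / (a + lam))
            logf0 = stats.nbinom.logpmf(0, a, a / (a + lam))
        if spec.is_two_part:
            cols = [sub[list(spec.zero_covariates)].to_numpy()]
            if spec.zero_intercept:
                cols.insert(0, np.ones((len(sub), 1)))
            Xz = np.column_stack(cols)
            E = sub[spec.zero_random_slope].to_numpy()
            u2 = (rng.normal(0.0, np.sqrt(params.v2), n_draws)
                  if params.v2 > 0 else np.zeros(n_draws))
            p = expit((Xz @ params.gamma)[:, None] + u2[None, :] * E[:, None])
            with np.errstate(divide="ignore"):
                if spec.is_hurdle:
                    ll = np.where(
                        y[:, None] == 0,
                        np.log(p),
                        np.log1p(-p) + base - np.log(-np.expm1(logf0)),
                    )
                else:
                    ll = np.where(
                        y[:, None] == 0,
                        np.log(p + (1.0 - p) * np.exp(logf0)),
                        np.log1p(-p) + base,
                    )
        else:
            ll = base
        cluster_ll = ll.sum(axis=0)                 # (n_draws,)
        log_mean = logsumexp(cluster_ll) - np.log(n_draws)
        # batched standard error: the importance weights can be heavy-tailed,
        # which makes the delta-method SE optimistic; the spread of batch
        # log-means is robust to that
        n_batch = 32
        usable = (n_draws // n_batch) * n_batch
        batches = cluster_ll[:usable].reshape(n_batch, -1)
        batch_logmeans = logsumexp(batches, axis=1) - np.log(batches.shape[1])
        se = batch_logmeans.std(ddof=1) / np.sqrt(n_batch)
        total += log_mean
        var += se ** 2
    return total, np.sqrt(var)
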