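"""Fit several families to one panel and rank them by AIC/BIC.

On data generated from the NB-mixed preset, the NB-mixed model should win:
the Poisson ignores overdispersion, the fixed-effects variants ignore the
county heterogeneity, and the zero-inflated/hurdle variants pay an AIC
penalty for zero-model parameters the data do not need.
"""

import firecount as fc
from firecount import ModelSpec

scenario = fc.reference_scenarios()["nb-mixed"]
panel = fc.generate_panel(scenario, seed=1)

covs = ("wind_max", "evaporation")
fits = []
for family in ("poisson", "nb", "zinb"):
    for effects in ("fixed", "mixed"):
        spec = ModelSpec(
            family, effects, covs,
            zero_covariates=("evaporation",) if family == "zinb" else (),
            zero_intercept=False,
        )
        fits.append(fc.fit(spec, panel, seed=0))

table = fc.compare_models(fits)
print(table[["model", "loglik", "k", "aic", "bic", "delta_aic",
             "best_aic"]].round(1).to_string(index=False))
# smaller AIC/BIC is better; BIC uses n = clusters for the mixed models and
# n = observations for the fixed ones
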