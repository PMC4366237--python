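"""Generate a synthetic county fire/weather panel and summarize it.

The NB-mixed preset draws monthly covariates from truncated normals matching
the reference spring-season summaries, then simulates fire counts from a
negative binomial model (theta = 0.99) whose log-mean carries a county
random intercept (variance 0.23).
"""

import firecount as fc

scenario = fc.reference_scenarios()["nb-mixed"]
panel = fc.generate_panel(scenario, seed=1)

print(panel)
print()
print(fc.summarize_covariates(panel).round(2))
print()
counts = panel.counts
print(f"counts: mean {counts.mean():.2f}, variance {counts.var(ddof=1):.2f}, "
      f"zero fraction {(counts == 0).mean():.3f}")
# variance far above the mean = overdispersion, the motivation for the NB
# family; the county random intercept adds between-county spread on top
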