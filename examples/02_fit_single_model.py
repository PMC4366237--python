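"""Fit one mixed-effects count model and read its parameter table.

Fits the NB model with a county random intercept (maximum likelihood via
adaptive Gauss-Hermite quadrature) to a synthetic panel generated from the
same family, so the estimates should sit near the generating values
(intercept 1.42, wind 0.09, evaporation -0.005, theta 0.99, v1 0.23).
"""

import firecount as fc

scenario = fc.reference_scenarios()["nb-mixed"]
panel = fc.generate_panel(scenario, seed=1)

result = fc.fit(scenario.spec, panel, seed=0)

print(result)
print()
print(result.to_frame().round(4).to_string(index=False))
# "estimate" is on the link scale: count-model coefficients act on log(mean),
# theta is the NB dispersion (variance = mean + theta*mean^2), v1 the
# county-intercept variance; ** marks p < 0.05, * marks p < 0.1
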