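"""Stepwise covariate selection on data with a planted weight effect.

Simulates 60 subjects whose clearance scales with weight^0.75, screens
random-effect/covariate pairs (Pearson and ANOVA on conditional samples) and
runs the forward-backward selection loop with the corrected-BIC guard.
"""

import salbupop as sp
from salbupop.covariates import CovariateEffect, stepwise_select
from salbupop.data import DesignSpec
from salbupop.initials import nca_informed_initials

truth = sp.PopModel(
    theta={"ka": 1.5, "cl": 5.0, "v1": 10.0, "q": 3.0, "v2": 20.0},
    omega={"ka": 0.15, "cl": 0.15, "v1": 0.15, "q": 0.15, "v2": 0.15},
    a=0.05, b=0.10,
    effects=(CovariateEffect("cl", "WT", "power", 0.75, 50.0),),
)
design = DesignSpec(times=(0.0, 0.25, 0.5, 1, 2, 3, 4, 6, 8, 12, 16, 24, 32, 48),
                    dose_ug=600)
dataset = sp.simulate_dataset(sp.sample_cohort(n=60, seed=21), truth, design,
                              seed=303)

fit, trace = stepwise_select(
    dataset,
    nca_informed_initials(dataset),
    candidates=[("cl", "WT"), ("cl", "AGE"), ("ka", "SEX")],
    settings=sp.SaemSettings(n_explore=120, n_smooth=80, seed=5, n_is=1000),
)
print(trace.to_frame().to_string(index=False))
print("final covariate effects:",
      [f"{e.label} (beta={e.beta:.2f})" for e in fit.model.effects])
# the planted weight-on-clearance effect is picked up with a tiny screening
# p-value and a large corrected-BIC drop; the two decoy candidates stay out
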