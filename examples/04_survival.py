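"""Treatment effect on mortality: Cox model with a proportional-hazards
check via a treatment x follow-up-time interaction.
"""

import math

import numpy as np

import agetraj as at

rng = np.random.default_rng(4)
design = at.StudyDesignSpec(n_per_sex_per_arm=60,
                            treatments=("control", "CQ"),
                            rolling_recruitment=False)
# treated males carry a 1.5-fold hazard (a harmful intervention)
mortality = at.MortalitySpec(family="exponential", rate=1 / 300.0,
                             log_hr_treatment={"CQ": math.log(1.5)})
mice = (at.apply_mortality(at.make_mice(0, 60, "control"), mortality, design, rng)
        + at.apply_mortality(at.make_mice(0, 60, "CQ"), mortality, design, rng))

records = at.survival_records(mice, design.max_age_days)
res = at.fit_cox(records, "CQ")
eff = res.treatment
print(f"events: {res.n_events}/{res.n}")
print(f"hazard ratio CQ vs control: {eff.hr:.2f} "
      f"(95% CI {eff.ci_low:.2f}-{eff.ci_high:.2f}, p={eff.p:.3g})")
p_ph = at.check_proportional_hazards(records, "CQ")
print(f"proportional-hazards check (treatment x time): p={p_ph:.2f}")

# Interpretation: the fitted HR should sit near the seeded 1.5 with a CI
# covering it, and the PH interaction p should be unremarkable because
# the simulated hazard ratio is constant over follow-up.
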