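"""Simulate a late-life aging cohort with mortality and rolling recruitment.

Builds two arms (untreated controls and an intervention) of 20 mice per
sex enrolled at 19 months, surveyed quarterly to 36 months under Gompertz
mortality, with dead animals replaced at later ages.  Prints the cohort
bookkeeping a study coordinator would track.
"""

import numpy as np

import agetraj as at

rng = np.random.default_rng(1)
design = at.StudyDesignSpec(n_per_sex_per_arm=20,
                            treatments=("control", "HBX"),
                            rolling_recruitment=True,
                            fracture_hazard_per_day=2e-4)
mortality = at.MortalitySpec()  # Gompertz, median lifespan ~27 months

mice = at.generate_cohort(design, mortality, rng)
frame = at.cohort_to_frame(mice)

n_initial = (frame["enroll_age_days"] == design.enroll_age_days).sum()
n_rolling = len(frame) - n_initial
n_dead = frame["death_age_days"].notna().sum()
print(f"animals enrolled: {len(frame)} "
      f"({n_initial} at baseline, {n_rolling} rolling replacements)")
print(f"deaths before 36 months: {n_dead}")

spec = at.GenerativeTraitSpec(
    "BV.TV", beta0=55.0, beta1_sex=2.0, beta3_slope=-1.941,
    beta4_interaction={"HBX": 0.604},
    sd_intercept=3.0, sd_slope=0.5, sd_residual=1.5)
obs = at.simulate_trait(mice, spec, design, rng)
fractures = at.simulate_fractures(mice, design, rng)
print(f"longitudinal scans simulated: {len(obs)}")
print(f"spontaneous fractures (all after 24 mo): {len(fractures)}")

# Interpretation: the cohort shrinks with age (mortality), replacements
# enter on later grid visits, and the bone trait declines 1.941 percent
# points per 100 days in controls but 0.604 points/100 d slower under the
# intervention -- the structure every downstream estimator assumes.
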