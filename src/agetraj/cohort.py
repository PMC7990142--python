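"""Synthetic aging-cohort generator.

Emulates the structure of a longitudinal mouse aging study: animals
enrolled per sex and treatment arm at ~19 months of age, surveyed on a
quarterly grid until death or a 36-month cap, with optional "rolling
recruitment" (dead animals replaced by new ones entering at later ages),
Gompertz or exponential mortality, Gaussian random-intercept/random-slope
trait trajectories on the per-100-days slope scale, rare femoral
fractures after 24 months, and spine centerlines whose true tortuosity
drifts upward with age.

All randomness flows from a single ``numpy.random.Generator``; module
functions derive deterministic substreams so that a fixed top-level seed
reproduces every output bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import SpineCenterline, arc_centerline

__all__ = [
    "DAYS_PER_MONTH",
    "MouseRecord",
    "ObservationRecord",
    "SpineObservation",
    "GenerativeTraitSpec",
    "MortalitySpec",
    "StudyDesignSpec",
    "generate_cohort",
    "make_mice",
    "apply_mortality",
    "simulate_trait",
    "simulate_fractures",
    "simulate_spines",
    "visit_schedule",
    "mouse_visit_ages",
    "cohort_to_frame",
    "observations_to_frame",
]

#: fixed month->day conversion (365.25 / 12); 19 mo = 578 d, 24 mo = 730 d,
#: 36 mo = 1095 d, matching the study's mixed months / per-100-days units.
DAYS_PER_MONTH = 30.44

SEXES = ("female", "male")


@dataclass(frozen=True)
class MouseRecord:
    """One animal: identity, arm, and (possibly censored) lifespan."""

    mouse_id: str
    sex: str
    treatment: str
    enroll_age_days: float
    death_age_days: float | None = None
    censored: bool = True

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex label {self.sex!r}")
        if self.death_age_days is not None and not (
            self.death_age_days > self.enroll_age_days
        ):
            raise ValueError("death age must exceed enrollment age")

    @property
    def exit_age_days(self) -> float | None:
        """Death age if dead, else None (exit set by the design cap)."""
        return self.death_age_days


@dataclass(frozen=True)
class ObservationRecord:
    """One phenotype value at one age for one mouse (long format)."""

    mouse_id: str
    phenotype: str
    age_days: float
    value: float

    def __post_init__(self) -> None:
        if not self.phenotype:
            raise ValueError("phenotype label must be non-empty")


@dataclass(frozen=True)
class SpineObservation:
    """A synthetic spine scan: who, when, the centerline, and the target
    tortuosity the centerline was built to realize."""

    mouse_id: str
    age_days: float
    spine: SpineCenterline
    target_tortuosity: float


@dataclass(frozen=True)
class GenerativeTraitSpec:
    """Generative twin of the longitudinal mixed model.

    A mouse's trajectory is

        y(t) = beta0 + beta1_sex*male + beta2[arm]
               + (beta3_slope + beta4_interaction[arm] + b_slope) * t
               + b_intercept + eps

    with t in units of 100 days since the study baseline, (b_intercept,
    b_slope) bivariate Gaussian and eps iid Gaussian.  Slopes are on the
    per-100-days reporting scale throughout.
    """

    phenotype: str
    beta0: float
    beta1_sex: float = 0.0
    beta3_slope: float = 0.0
    beta4_interaction: dict[str, float] = field(default_factory=dict)
    beta2_treatment: dict[str, float] = field(default_factory=dict)
    sd_intercept: float = 0.0
    sd_slope: float = 0.0
    sd_residual: float = 0.0
    corr_intercept_slope: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sd_intercept", "sd_slope", "sd_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1.0 <= self.corr_intercept_slope <= 1.0:
            raise ValueError("intercept-slope correlation must lie in [-1, 1]")


@dataclass(frozen=True)
class MortalitySpec:
    """Baseline hazard plus proportional log-hazard shifts.

    family "exponential": h(t) = rate.
    family "gompertz":    h(t) = a * exp(b * t), t = age in days.
    ``log_hr_sex`` applies to males; ``log_hr_treatment`` maps arm labels
    to log hazard ratios (missing arms get 0).
    """

    family: str = "gompertz"
    rate: float = 0.0                     # exponential rate per day
    gompertz_a: float = 7.5e-6            # per day
    gompertz_b: float = 0.008             # per day
    log_hr_sex: float = 0.0
    log_hr_treatment: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in ("exponential", "gompertz"):
            raise ValueError(f"unknown hazard family {self.family!r}")
        if self.family == "exponential" and self.rate < 0:
            raise ValueError("exponential rate must be >= 0")
        if self.family == "gompertz" and (self.gompertz_a < 0 or self.gompertz_b < 0):
            raise ValueError("Gompertz parameters must be >= 0")

    def log_hr(self, sex: str, treatment: str) -> float:
        lhr = self.log_hr_treatment.get(treatment, 0.0)
        if sex == "male":
            lhr += self.log_hr_sex
        return lhr

    @classmethod
    def none(cls) -> "MortalitySpec":
        """Zero mortality (every animal survives to the follow-up cap)."""
        return cls(family="exponential", rate=0.0)


@dataclass(frozen=True)
class StudyDesignSpec:
    """Cohort layout and surveillance schedule.

    Defaults mirror the study: ~20 animals per sex per arm, quarterly
    visits (91 d) from a 19-month baseline up to 36 months, rolling
    recruitment on, rare fractures only after 24 months.
    """

    n_per_sex_per_arm: int = 20
    treatments: tuple[str, ...] = ("control",)
    enroll_age_days: float = 578.0        # ~19 mo
    visit_spacing_days: float = 91.0      # ~quarterly
    max_age_days: float = 1095.0          # ~36 mo
    rolling_recruitment: bool = True
    fracture_hazard_per_day: float = 0.0  # applies only at age >= fracture_min_age
    fracture_min_age_days: float = 730.0  # ~24 mo
    visit_jitter_days: float = 0.0        # optional +/- uniform jitter

    def __post_init__(self) -> None:
        if self.n_per_sex_per_arm < 1:
            raise ValueError("need at least one mouse per sex per arm")
        if self.visit_spacing_days <= 0:
            raise ValueError("visit spacing must be positive")
        if self.max_age_days <= self.enroll_age_days:
            raise ValueError("max follow-up age must exceed enrollment age")
        if len(set(self.treatments)) != len(self.treatments) or not self.treatments:
            raise ValueError("treatment labels must be non-empty and unique")


# ---------------------------------------------------------------------------
# mortality draws

def _draw_death_age(
    rng: np.random.Generator, mortality: MortalitySpec, entry_age: float, log_hr: float
) -> float:
    """Death age conditional on being alive at ``entry_age`` (inverse CDF)."""
    u = rng.uniform()
    scale = math.exp(log_hr)
    if mortality.family == "exponential":
        rate = mortality.rate * scale
        if rate <= 0.0:
            return math.inf
        return entry_age - math.log(u) / rate
    a = mortality.gompertz_a * scale
    b = mortality.gompertz_b
    if a <= 0.0:
        return math.inf
    if b == 0.0:
        return entry_age - math.log(u) / a
    # S(t | t0) = exp(-(a/b) (e^{bt} - e^{bt0}))
    return math.log(math.exp(b * entry_age) - b * math.log(u) / a) / b


# ---------------------------------------------------------------------------
# schedule helpers

def visit_schedule(design: StudyDesignSpec) -> np.ndarray:
    """Global surveillance grid: enrollment age, then every spacing, capped."""
    n = int(math.floor((design.max_age_days - design.enroll_age_days)
                       / design.visit_spacing_days)) + 1
    return design.enroll_age_days + design.visit_spacing_days * np.arange(n)

def mouse_visit_ages(
    mouse: MouseRecord,
    design: StudyDesignSpec,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Scheduled visit ages this mouse is alive for.

    Visits run on the global grid; a replacement animal joins at its first
    grid age at or after its (later) enrollment.  A mouse contributes no
    visit on or after its death day.
    """
    grid = visit_schedule(design)
    ages = grid[grid >= mouse.enroll_age_days - 1e-9]
    if mouse.death_age_days is not None:
        ages = ages[ages < mouse.death_age_days]
    if design.visit_jitter_days > 0 and rng is not None and ages.size:
        jitter = rng.uniform(-design.visit_jitter_days, design.visit_jitter_days,
                             size=ages.size)
        ages = ages + jitter
    return ages


# ---------------------------------------------------------------------------
# generation

def generate_cohort(
    design: StudyDesignSpec,
    mortality: MortalitySpec,
    rng: np.random.Generator,
) -> list[MouseRecord]:
    """Generate animals for every arm x sex cell, with mortality and
    (optionally) rolling recruitment.

    Each cell starts with ``n_per_sex_per_arm`` animals at the baseline
    age.  When rolling recruitment is on, an animal that dies before the
    follow-up cap is replaced by a new animal entering at the next grid
    visit after the death, provided at least two visits remain (a
    repeated-measures design needs two scans to contribute).
    """
    grid = visit_schedule(design)
    last_useful_entry = grid[-2] if grid.size >= 2 else grid[-1]
    mice: list[MouseRecord] = []
    for treatment in design.treatments:
        for sex in SEXES:
            counter = 0
            pending = [design.enroll_age_days] * design.n_per_sex_per_arm
            while pending:
                entry = pending.pop(0)
                counter += 1
                mouse_id = f"{treatment}-{sex[0]}{counter:04d}"
                death = _draw_death_age(rng, mortality, entry,
                                        mortality.log_hr(sex, treatment))
                if death >= design.max_age_days:
                    rec = MouseRecord(mouse_id, sex, treatment, entry,
                                      death_age_days=None, censored=True)
                else:
                    rec = MouseRecord(mouse_id, sex, treatment, entry,
                                      death_age_days=death, censored=False)
                    if design.rolling_recruitment:
                        nxt = grid[grid > death]
                        if nxt.size and nxt[0] <= last_useful_entry + 1e-9:
                            pending.append(float(nxt[0]))
                mice.append(rec)
    return mice


def make_mice(
    n_female: int,
    n_male: int,
    treatment: str = "control",
    enroll_age_days: float = 578.0,
) -> list[MouseRecord]:
    """Immortal cohort with explicit per-sex counts (e.g. the study's 50
    male / 39 female control bone cohort); useful for seeded-recovery
    simulations where attrition is not part of the question."""
    mice = [MouseRecord(f"{treatment}-f{i:04d}", "female", treatment,
                        enroll_age_days) for i in range(n_female)]
    mice += [MouseRecord(f"{treatment}-m{i:04d}", "male", treatment,
                         enroll_age_days) for i in range(n_male)]
    return mice


def apply_mortality(
    mice: list[MouseRecord],
    mortality: MortalitySpec,
    design: StudyDesignSpec,
    rng: np.random.Generator,
) -> list[MouseRecord]:
    """Draw a death age for each mouse of an existing cohort (e.g. one
    built with :func:`make_mice`), censoring at the design's age cap."""
    out: list[MouseRecord] = []
    for m in mice:
        death = _draw_death_age(rng, mortality, m.enroll_age_days,
                                mortality.log_hr(m.sex, m.treatment))
        if death >= design.max_age_days:
            out.append(MouseRecord(m.mouse_id, m.sex, m.treatment,
                                   m.enroll_age_days, None, True))
        else:
            out.append(MouseRecord(m.mouse_id, m.sex, m.treatment,
                                   m.enroll_age_days, death, False))
    return out


def simulate_trait(
    mice: list[MouseRecord],
    spec: GenerativeTraitSpec,
    design: StudyDesignSpec,
    rng: np.random.Generator,
) -> list[ObservationRecord]:
    """Longitudinal values for one phenotype at every visit each mouse
    survives to.

    Time is measured in units of 100 days since the design's baseline
    (enrollment) age, so ``spec`` slopes are on the per-100-days reporting
    scale.  Random effects are drawn per mouse; residuals per visit.
    """
    s0, s1 = spec.sd_intercept, spec.sd_slope
    rho = spec.corr_intercept_slope
    # explicit Cholesky factor; valid for any rho in [-1, 1] incl. zero SDs
    chol = np.array([[s0, 0.0],
                     [rho * s1, s1 * math.sqrt(max(1.0 - rho * rho, 0.0))]])
    out: list[ObservationRecord] = []
    for mouse in mice:
        ages = mouse_visit_ages(mouse, design, rng)
        b0, b3 = chol @ rng.standard_normal(2)
        male = 1.0 if mouse.sex == "male" else 0.0
        slope = (spec.beta3_slope
                 + spec.beta4_interaction.get(mouse.treatment, 0.0)
                 + b3)
        level = (spec.beta0
                 + spec.beta1_sex * male
                 + spec.beta2_treatment.get(mouse.treatment, 0.0)
                 + b0)
        if ages.size == 0:
            continue
        t100 = (ages - design.enroll_age_days) / 100.0
        eps = (rng.standard_normal(ages.size) * spec.sd_residual
               if spec.sd_residual > 0 else np.zeros(ages.size))
        values = level + slope * t100 + eps
        out.extend(
            ObservationRecord(mouse.mouse_id, spec.phenotype, float(a), float(v))
            for a, v in zip(ages, values)
        )
    return out


def simulate_fractures(
    mice: list[MouseRecord],
    design: StudyDesignSpec,
    rng: np.random.Generator,
) -> list[tuple[str, float]]:
    """First spontaneous fracture per mouse, if any.

    Fracture risk is a constant hazard that switches on at
    ``fracture_min_age_days`` (~24 months; no fractures occur before that
    age) and runs while the animal is alive and under follow-up.
    """
    h = design.fracture_hazard_per_day
    events: list[tuple[str, float]] = []
    if h <= 0:
        return events
    for mouse in mice:
        start = max(mouse.enroll_age_days, design.fracture_min_age_days)
        end = min(mouse.death_age_days or math.inf, design.max_age_days)
        if end <= start:
            continue
        t = start - math.log(rng.uniform()) / h
        if t < end:
            events.append((mouse.mouse_id, float(t)))
    return events


def simulate_spines(
    mice: list[MouseRecord],
    design: StudyDesignSpec,
    tortuosity_trait: GenerativeTraitSpec,
    rng: np.random.Generator,
    n_points: int = 100,
) -> list[SpineObservation]:
    """Spine centerlines whose true tortuosity follows the trait model.

    The target tortuosity for each mouse-visit comes from
    :func:`simulate_trait`; each centerline is a circular arc (at a random
    rigid pose) constructed so that scoring it with
    :func:`agetraj.geometry.compute_tortuosity` returns the target to
    within 1e-6.  Targets must lie in [0, 1).
    """
    obs = simulate_trait(mice, tortuosity_trait, design, rng)
    spines: list[SpineObservation] = []
    for o in obs:
        if not 0.0 <= o.value < 1.0:
            raise ValueError(
                f"target tortuosity {o.value:g} for {o.mouse_id} outside [0, 1); "
                "adjust the generative spec"
            )
        spine = arc_centerline(o.value, n_points=n_points, rng=rng)
        spines.append(SpineObservation(o.mouse_id, o.age_days, spine, o.value))
    return spines


# ---------------------------------------------------------------------------
# frames

def cohort_to_frame(mice: list[MouseRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mouse_id": [m.mouse_id for m in mice],
            "sex": [m.sex for m in mice],
            "treatment": [m.treatment for m in mice],
            "enroll_age_days": [m.enroll_age_days for m in mice],
            "death_age_days": [m.death_age_days for m in mice],
            "censored": [m.censored for m in mice],
        }
    )


def observations_to_frame(obs: list[ObservationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mouse_id": [o.mouse_id for o in obs],
            "phenotype": [o.phenotype for o in obs],
            "age_days": [o.age_days for o in obs],
            "value": [o.value for o in obs],
        }
    )
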