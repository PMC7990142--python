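"""Sample-size and power for detecting differences in age-slopes.

The design question: how many mice per group are needed for 80% power to
detect a given percent difference in the age-associated rate of change of
a trait, with k repeated observations at fixed spacing?  The inputs are
the variance components estimated by the longitudinal mixed model.

A single mouse observed at times t_1..t_k has estimated-slope variance

    V = sd_slope^2 + sd_residual^2 / S_xx,   S_xx = sum_j (t_j - tbar)^2

and the two-group normal-approximation sample size for a slope
difference d is

    N = 2 (z_{1-a/2} + z_{power})^2 V / d^2   per group,

with d = |control slope| * effect_percent / 100.  Attrition inflates N by
the reciprocal of the expected completeness of the visit schedule.  The
formula is verified against a Monte-Carlo oracle that simulates two-arm
cohorts through the synthetic-cohort generator and tests the slope
contrast per replicate; the oracle, not the formula, is the ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (GenerativeTraitSpec, StudyDesignSpec,
                     observations_to_frame, simulate_trait)
from .longitudinal import VarianceComponents, fit_trajectory

__all__ = [
    "PowerQuery",
    "PowerTable",
    "slope_variance_per_mouse",
    "sample_size",
    "monte_carlo_power",
    "power_table",
]


@dataclass(frozen=True)
class PowerQuery:
    """One cell of the design resource: variance components, the control
    slope (per 100 days), the percent slope difference to detect, and the
    visit schedule."""

    variance_components: VarianceComponents
    control_slope_per_100d: float
    effect_percent: float
    n_visits: int
    visit_spacing_days: float = 100.0
    alpha: float = 0.05
    power: float = 0.80
    attrition_per_interval: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.power < 1.0:
            raise ValueError("power must lie in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_visits < 2:
            raise ValueError("need at least 2 visits to estimate a slope")
        if self.effect_percent <= 0:
            raise ValueError("effect size must be positive")
        if self.visit_spacing_days <= 0:
            raise ValueError("visit spacing must be positive")
        if not 0.0 <= self.attrition_per_interval < 1.0:
            raise ValueError("attrition must lie in [0, 1)")


def slope_variance_per_mouse(
    vc: VarianceComponents, n_visits: int, spacing_days: float
) -> float:
    """Variance of one mouse's OLS-estimated slope, per-100-days scale.

    sd_slope^2 + sd_residual^2 / S_xx with visit times (j-1)*spacing
    converted to 100-day units.
    """
    if n_visits < 2:
        raise ValueError("need at least 2 visits")
    t = np.arange(n_visits) * (spacing_days / 100.0)
    sxx = float(np.sum((t - t.mean()) ** 2))
    return vc.sd_slope_per_100d ** 2 + vc.sd_residual ** 2 / sxx


def _expected_completeness(n_visits: int, attrition: float) -> float:
    """Mean fraction of the schedule completed under per-interval
    independent dropout with monotone loss to follow-up."""
    retain = (1.0 - attrition) ** np.arange(n_visits)
    return float(retain.mean())


def sample_size(query: PowerQuery, use_t: bool = False) -> int:
    """Per-group N (ceiling, minimum 2) for the requested power.

    ``use_t`` iterates the calculation with t quantiles (df = 2N - 2)
    instead of normal quantiles; at the N ranges of interest the two
    rarely differ by more than one animal.
    """
    if query.control_slope_per_100d == 0:
        raise ValueError("sample size undefined for a zero control slope")
    d = abs(query.control_slope_per_100d) * query.effect_percent / 100.0
    v = slope_variance_per_mouse(
        query.variance_components, query.n_visits, query.visit_spacing_days
    )
    if v == 0.0:
        return 2
    completeness = _expected_completeness(query.n_visits,
                                          query.attrition_per_interval)
    za = stats.norm.ppf(1.0 - query.alpha / 2.0)
    zb = stats.norm.ppf(query.power)
    n = 2.0 * (za + zb) ** 2 * v / d ** 2 / completeness
    if use_t:
        for _ in range(8):
            df = max(2.0 * n - 2.0, 2.0)
            ta = stats.t.ppf(1.0 - query.alpha / 2.0, df)
            tb = stats.t.ppf(query.power, df)
            n = 2.0 * (ta + tb) ** 2 * v / d ** 2 / completeness
    return max(int(math.ceil(n)), 2)


def _simulate_arm_design(query: PowerQuery) -> StudyDesignSpec:
    span = (query.n_visits - 1) * query.visit_spacing_days
    return StudyDesignSpec(
        n_per_sex_per_arm=1,  # unused; cohorts built directly below
        treatments=("control", "treated"),
        enroll_age_days=578.0,
        visit_spacing_days=query.visit_spacing_days,
        max_age_days=578.0 + span + 1.0,
        rolling_recruitment=False,
    )


def monte_carlo_power(
    query: PowerQuery,
    n_per_group: int,
    n_reps: int = 1000,
    seed: int | np.random.Generator = 0,
    method: str = "slope_ttest",
) -> float:
    """Empirical power: fraction of simulated two-arm studies rejecting
    the slope-equality null at the query's alpha.

    Each replicate simulates a control and a treated arm through the
    synthetic-cohort generator (treated slope = control slope scaled by
    1 - effect/100), with optional monotone per-interval dropout.
    ``method="slope_ttest"`` tests the per-mouse OLS slopes with Welch's
    t (the slope is the sufficient per-mouse summary on this balanced
    grid); ``method="lmm"`` refits the full mixed model per replicate and
    tests the treatment x age interaction.  Both are true simulation
    oracles; the t-test path is the fast default.
    """
    if method not in ("slope_ttest", "lmm"):
        raise ValueError(f"unknown method {method!r}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    vc = query.variance_components
    slope_c = query.control_slope_per_100d
    slope_t = slope_c * (1.0 - query.effect_percent / 100.0)
    if method == "lmm":
        return _mc_power_lmm(query, n_per_group, n_reps, rng, slope_c, slope_t)

    k = query.n_visits
    t = np.arange(k) * (query.visit_spacing_days / 100.0)
    rejections = 0
    n_valid = 0
    for _ in range(n_reps):
        slopes = []
        for true_slope in (slope_c, slope_t):
            y = _simulate_arm_matrix(rng, vc, true_slope, t, n_per_group)
            n_done = _dropout_visit_counts(rng, n_per_group, k,
                                           query.attrition_per_interval)
            slopes.append(_per_mouse_slopes(y, t, n_done))
        b, a = slopes  # control, treated
        if len(a) < 2 or len(b) < 2:
            continue
        _, p = stats.ttest_ind(a, b, equal_var=False)
        if np.isfinite(p):
            n_valid += 1
            if p < query.alpha:
                rejections += 1
    if n_valid == 0:
        raise RuntimeError("no valid replicates")
    return rejections / n_valid


def _simulate_arm_matrix(rng, vc, true_slope, t, n) -> np.ndarray:
    """(n, k) trait matrix from the random-intercept/slope model."""
    rho = vc.corr_intercept_slope
    z = rng.standard_normal((n, 2))
    b0 = vc.sd_intercept * z[:, 0]
    b3 = vc.sd_slope_per_100d * (rho * z[:, 0]
                                 + math.sqrt(max(1 - rho * rho, 0.0)) * z[:, 1])
    eps = rng.standard_normal((n, t.size)) * vc.sd_residual
    return b0[:, None] + (true_slope + b3)[:, None] * t[None, :] + eps


def _dropout_visit_counts(rng, n, k, attrition) -> np.ndarray:
    """Completed visit count per mouse under monotone per-interval dropout."""
    if attrition <= 0:
        return np.full(n, k, dtype=int)
    # mouse survives each of the k-1 inter-visit intervals independently
    surv = rng.uniform(size=(n, k - 1)) >= attrition
    return 1 + np.cumprod(surv, axis=1).sum(axis=1).astype(int)


def _per_mouse_slopes(y: np.ndarray, t: np.ndarray, n_done: np.ndarray
                      ) -> np.ndarray:
    """OLS slope of each mouse's first n_done visits (needs >= 2)."""
    slopes = []
    full = int(t.size)
    # vectorized fast path for the (typical) complete-schedule mice
    tc = t - t.mean()
    sxx = float(tc @ tc)
    complete = n_done >= full
    if complete.any():
        yc = y[complete] - y[complete].mean(axis=1, keepdims=True)
        slopes.extend((yc @ tc) / sxx)
    for i in np.nonzero(~complete)[0]:
        m = int(n_done[i])
        if m < 2:
            continue
        ti = t[:m] - t[:m].mean()
        slopes.append(float(ti @ (y[i, :m] - y[i, :m].mean()) / (ti @ ti)))
    return np.asarray(slopes)


def _mc_power_lmm(query, n_per_group, n_reps, rng, slope_c, slope_t) -> float:
    """Slow oracle path: full mixed-model refit per replicate."""
    from .cohort import MouseRecord

    vc = query.variance_components
    design = _simulate_arm_design(query)
    spec = GenerativeTraitSpec(
        phenotype="trait",
        beta0=0.0,
        beta3_slope=slope_c,
        beta4_interaction={"treated": slope_t - slope_c},
        sd_intercept=vc.sd_intercept,
        sd_slope=vc.sd_slope_per_100d,
        sd_residual=vc.sd_residual,
        corr_intercept_slope=vc.corr_intercept_slope,
    )
    mice = [
        MouseRecord(f"{arm}-{i:04d}", "female" if i % 2 else "male", arm,
                    design.enroll_age_days)
        for arm in ("control", "treated")
        for i in range(n_per_group)
    ]
    coh = pd.DataFrame({
        "mouse_id": [m.mouse_id for m in mice],
        "sex": [m.sex for m in mice],
        "treatment": [m.treatment for m in mice],
    })
    rejections = n_valid = 0
    for _ in range(n_reps):
        obs = simulate_trait(mice, spec, design, rng)
        df = observations_to_frame(obs)
        fit = fit_trajectory(df, coh, "trait", "treated",
                             baseline_age_days=design.enroll_age_days,
                             sex_interaction=False)
        p = fit.beta4_interaction.p
        if p is not None and np.isfinite(p):
            n_valid += 1
            if p < query.alpha:
                rejections += 1
    if n_valid == 0:
        raise RuntimeError("no valid replicates")
    return rejections / n_valid


@dataclass(frozen=True)
class PowerTable:
    """Per-group N over an effect-percent x visits grid."""

    grid: pd.DataFrame  # index: effect_percent, columns: n_visits
    control_slope_per_100d: float
    visit_spacing_days: float

    def n_for(self, effect_percent: float, n_visits: int) -> int:
        return int(self.grid.loc[effect_percent, n_visits])


def power_table(
    vc: VarianceComponents,
    control_slope_per_100d: float,
    effects_percent=(5.0, 10.0, 15.0, 20.0, 25.0, 50.0),
    visits=range(3, 10),
    visit_spacing_days: float = 100.0,
    alpha: float = 0.05,
    power: float = 0.80,
    attrition_per_interval: float = 0.0,
) -> PowerTable:
    """The design-resource grid: per-group N for each effect size and
    number of repeated observations (3-9 by default).

    N is checked to be nonincreasing along both axes (larger effects and
    more visits never require more animals at fixed spacing).
    """
    effects = [float(e) for e in effects_percent]
    visits = [int(k) for k in visits]
    data = {}
    for k in visits:
        col = []
        for e in effects:
            q = PowerQuery(vc, control_slope_per_100d, e, k,
                           visit_spacing_days, alpha, power,
                           attrition_per_interval)
            col.append(sample_size(q))
        data[k] = col
    grid = pd.DataFrame(data, index=pd.Index(effects, name="effect_percent"))
    grid.columns.name = "n_visits"
    if (grid.diff(axis=0).fillna(0) > 0).any().any():
        raise AssertionError("sample size must be nonincreasing in effect size")
    if (grid.diff(axis=1).fillna(0) > 0).any().any():
        raise AssertionError("sample size must be nonincreasing in visit count")
    return PowerTable(grid, control_slope_per_100d, visit_spacing_days)
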