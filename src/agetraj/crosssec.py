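"""Cross-sectional young-vs-aged comparisons and fracture incidence.

Young (e.g. 5-month) and middle-aged (19-month) groups are different
animals, so group means are compared with unpaired t-tests (Welch by
default) or a sex-adjusted linear model; age-related changes in spread
are tested with the Brown-Forsythe (median-centered Levene) statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from .cohort import cohort_to_frame, observations_to_frame

__all__ = [
    "GroupComparison",
    "compare_groups",
    "compare_variances",
    "fracture_frequency",
]


@dataclass(frozen=True)
class GroupComparison:
    phenotype: str
    n_young: int
    n_old: int
    beta: float            # mean difference, old - young
    se: float
    p: float
    variance_ratio: float | None = None
    p_variance: float | None = None


def _group_values(obs, phenotype: str) -> pd.DataFrame:
    df = obs if isinstance(obs, pd.DataFrame) else observations_to_frame(list(obs))
    df = df[df["phenotype"] == phenotype]
    if df.empty:
        raise ValueError(f"no observations for phenotype {phenotype!r}")
    return df


def compare_groups(
    obs_young,
    obs_old,
    phenotype: str,
    adjust_sex: bool = False,
    cohort=None,
    equal_var: bool = False,
) -> GroupComparison:
    """Unpaired comparison of group means (beta = old - young).

    Welch's t-test by default (``equal_var=True`` switches to the pooled
    test).  With ``adjust_sex`` the difference comes from a linear model
    with a sex covariate, which requires ``cohort`` to map mice to sex.
    """
    young = _group_values(obs_young, phenotype)
    old = _group_values(obs_old, phenotype)
    if len(young) < 2 or len(old) < 2:
        raise ValueError("each group needs at least 2 observations")

    if adjust_sex:
        if cohort is None:
            raise ValueError("adjust_sex requires the cohort table")
        coh = cohort if isinstance(cohort, pd.DataFrame) else cohort_to_frame(list(cohort))
        df = pd.concat(
            [young.assign(old=0.0), old.assign(old=1.0)], ignore_index=True
        ).merge(coh[["mouse_id", "sex"]], on="mouse_id", how="inner")
        df["male"] = (df["sex"] == "male").astype(float)
        res = smf.ols("value ~ old + male", data=df).fit()
        beta = float(res.params["old"])
        se = float(res.bse["old"])
        p = float(res.pvalues["old"])
    else:
        a, b = old["value"].to_numpy(), young["value"].to_numpy()
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        beta = float(a.mean() - b.mean())
        se = float(np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
                   if not equal_var else abs(beta / t) if t != 0 else np.nan)
        p = float(p)
    vr, pv = None, None
    try:
        vr, pv = compare_variances(obs_young, obs_old, phenotype)
    except ValueError:
        pass
    return GroupComparison(phenotype, len(young), len(old), beta, se, p, vr, pv)


def compare_variances(obs_young, obs_old, phenotype: str) -> tuple[float, float]:
    """Age-related change in spread: variance ratio old/young plus the
    Brown-Forsythe (median-centered Levene) p-value."""
    young = _group_values(obs_young, phenotype)["value"].to_numpy()
    old = _group_values(obs_old, phenotype)["value"].to_numpy()
    vy, vo = young.var(ddof=1), old.var(ddof=1)
    if vy == 0 or vo == 0:
        raise ValueError("variance comparison undefined for a constant group")
    _, p = stats.levene(young, old, center="median")
    return float(vo / vy), float(p)


def fracture_frequency(
    mice,
    observations,
    fractures: list[tuple[str, float]],
    min_age_days: float = 730.0,
) -> tuple[int, int, float]:
    """Fracture incidence among animals scanned at or beyond ``min_age_days``.

    Returns (k, n, percent): n distinct mice with at least one scan at
    age >= min_age_days, k of those with a recorded fracture, and
    100 k / n rounded to one decimal.
    """
    obs = (observations if isinstance(observations, pd.DataFrame)
           else observations_to_frame(list(observations)))
    at_risk = set(obs.loc[obs["age_days"] >= min_age_days, "mouse_id"])
    if mice is not None:
        coh = mice if isinstance(mice, pd.DataFrame) else cohort_to_frame(list(mice))
        at_risk &= set(coh["mouse_id"])
    n = len(at_risk)
    if n == 0:
        raise ValueError("no mice scanned at or beyond the minimum age")
    k = len({mid for mid, _age in fractures} & at_risk)
    return k, n, round(100.0 * k / n, 1)
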