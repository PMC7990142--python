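"""Treatment effects on mortality via Cox proportional-hazards models.

The hazard of death is modeled as

    h(t | x) = h0(t) * exp(b1 * male + b2 * treated)

with t the follow-up time since study entry (age-as-time with left
truncation by entry age is available by flag).  One model is fit per
treatment arm against the controls; the null hypothesis is b2 = 0 and
HR = exp(b2).  Ties are handled with Efron's method (rodent death days
are heavily tied).  Proportionality is checked the way the source design
prescribes: by adding a treatment x follow-up-time interaction (episode
splitting at event times) and testing its coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter
from lifelines.utils import to_episodic_format

from .cohort import MouseRecord, cohort_to_frame

__all__ = [
    "CovariateEffect",
    "CoxResult",
    "survival_records",
    "fit_cox",
    "check_proportional_hazards",
]


@dataclass(frozen=True)
class CovariateEffect:
    hr: float
    ci_low: float
    ci_high: float
    p: float
    coef: float
    se: float


@dataclass
class CoxResult:
    effects: dict[str, CovariateEffect]
    n: int
    n_events: int
    log_likelihood: float
    log_likelihood_null: float

    @property
    def treatment(self) -> CovariateEffect:
        return self.effects["treat"]


def survival_records(
    mice: list[MouseRecord] | pd.DataFrame,
    max_age_days: float = 1095.0,
) -> pd.DataFrame:
    """One row per mouse: entry/exit age in days and the death indicator.

    Animals alive at ``max_age_days`` are censored there.
    """
    coh = mice if isinstance(mice, pd.DataFrame) else cohort_to_frame(list(mice))
    death = pd.to_numeric(coh["death_age_days"], errors="coerce")
    exit_age = death.fillna(max_age_days).clip(upper=max_age_days)
    event = death.notna() & (death <= max_age_days)
    df = pd.DataFrame({
        "mouse_id": coh["mouse_id"],
        "entry_age_days": coh["enroll_age_days"].astype(float),
        "exit_age_days": exit_age.astype(float),
        "event": event.astype(int),
        "sex": coh["sex"],
        "treatment": coh["treatment"],
    })
    if (df["exit_age_days"] <= df["entry_age_days"]).any():
        raise ValueError("exit age must exceed entry age for every mouse")
    return df


def _design_frame(records: pd.DataFrame, treatment: str, control_label: str,
                  adjust_sex: bool, age_as_time: bool) -> pd.DataFrame:
    df = records[records["treatment"].isin([control_label, treatment])].copy()
    if df.empty:
        raise ValueError(f"no records for arm {treatment!r} or controls")
    df["treat"] = (df["treatment"] == treatment).astype(float)
    df["male"] = (df["sex"] == "male").astype(float)
    if age_as_time:
        df["time"] = df["exit_age_days"]
        df["entry"] = df["entry_age_days"]
    else:
        df["time"] = df["exit_age_days"] - df["entry_age_days"]
        df["entry"] = 0.0
    if int(df["event"].sum()) == 0:
        raise ValueError("no death events: Cox model is not estimable")
    return df


def fit_cox(
    records: pd.DataFrame,
    treatment: str,
    *,
    control_label: str = "control",
    adjust_sex: bool = True,
    stratify_sex: bool = False,
    age_as_time: bool = False,
) -> CoxResult:
    """Cox partial-likelihood fit of one treatment arm against controls.

    ``adjust_sex`` adds male as a covariate; ``stratify_sex`` instead
    allows sex-specific baseline hazards.  ``age_as_time`` switches the
    time axis from time-on-study to age with left truncation at entry.
    Complete separation (a monotone likelihood) is surfaced as a
    ConvergenceError from the fitter.
    """
    df = _design_frame(records, treatment, control_label, adjust_sex, age_as_time)
    covs = ["treat"] + (["male"] if adjust_sex and not stratify_sex
                        and df["male"].nunique() > 1 else [])
    cols = ["time", "event", "entry"] + covs + (["male"] if stratify_sex else [])
    cph = CoxPHFitter()
    cph.fit(
        df[cols],
        duration_col="time",
        event_col="event",
        entry_col="entry" if age_as_time else None,
        strata=["male"] if stratify_sex else None,
        formula=" + ".join(covs),
    )
    effects = {}
    for name in covs:
        coef = float(cph.params_[name])
        se = float(cph.standard_errors_[name])
        ci = cph.confidence_intervals_
        effects[name] = CovariateEffect(
            hr=float(np.exp(coef)),
            ci_low=float(np.exp(ci.loc[name].iloc[0])),
            ci_high=float(np.exp(ci.loc[name].iloc[1])),
            p=float(cph.summary.loc[name, "p"]),
            coef=coef,
            se=se,
        )
    lr = cph.log_likelihood_ratio_test()
    ll = float(cph.log_likelihood_)
    return CoxResult(
        effects=effects,
        n=int(len(df)),
        n_events=int(df["event"].sum()),
        log_likelihood=ll,
        log_likelihood_null=ll - float(lr.test_statistic) / 2.0,
    )


def check_proportional_hazards(
    records: pd.DataFrame,
    treatment: str,
    *,
    control_label: str = "control",
    adjust_sex: bool = True,
) -> float:
    """p-value for a treatment x follow-up-time interaction.

    The follow-up axis is split into episodes at the observed event times
    and the model gains a time-varying covariate treat * t; under
    proportional hazards its coefficient is zero and the p-value is
    uniform.
    """
    df = _design_frame(records, treatment, control_label, adjust_sex,
                       age_as_time=False)
    covs = ["treat"] + (["male"] if adjust_sex and df["male"].nunique() > 1 else [])
    base = df[["mouse_id", "time", "event"] + covs].copy()
    long = to_episodic_format(base, duration_col="time", event_col="event")
    long["treat_x_t"] = long["treat"] * long["stop"]
    ctv = CoxTimeVaryingFitter()
    ctv.fit(
        long[["id", "start", "stop", "event"] + covs + ["treat_x_t"]],
        id_col="id",
        start_col="start",
        stop_col="stop",
        event_col="event",
    )
    return float(ctv.summary.loc["treat_x_t", "p"])
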