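"""Mixed-effects estimation of age-related trajectories.

For each phenotype the mouse-specific model

    y_ij = b0 + b1*male_i + b2*treat_i + b3*t_ij + b4*treat_i*t_ij
           + u0_i + u3_i * t_ij + e_ij

is fit by REML, where t_ij is the age of mouse i at observation j in
units of 100 days since the 19-month study baseline (so fixed and random
slopes are reported per 100 days), (u0_i, u3_i) are Gaussian
random intercept/slope deviations and e_ij is residual noise.  When no
treatment arm is requested the b2/b4 terms are omitted and the fit
returns the controls-only aging rate.  The treatment x age coefficient
b4 is the intervention effect on the rate of change; expressed as a
fraction of the control slope it is the "sparing" percentage.

Wald t-tests use residual degrees of freedom (n_obs - n_fixed); the fit
records the df method used.  Non-converged fits fall back along a ladder
(free intercept/slope covariance -> independent random effects -> random
intercept only), logging each step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline
import statsmodels.formula.api as smf

from .cohort import (ObservationRecord, cohort_to_frame,
                     observations_to_frame)

__all__ = [
    "Estimate",
    "VarianceComponents",
    "TrajectoryFit",
    "fit_trajectory",
    "fit_trajectory_by_sex",
    "drop_singletons_and_post_fracture",
    "annualize_rate",
    "sparing_percent",
    "qvalues",
    "trajectory_table",
    "BASELINE_AGE_DAYS",
]

#: 19-month study baseline used to center age
BASELINE_AGE_DAYS = 578.0


@dataclass(frozen=True)
class Estimate:
    value: float
    se: float
    p: float


@dataclass(frozen=True)
class VarianceComponents:
    """Random-effect and residual SDs on the per-100-days time scale.

    These are the currency between trajectory fitting and the
    repeated-measures power calculations.
    """

    sd_intercept: float
    sd_slope_per_100d: float
    corr_intercept_slope: float
    sd_residual: float

    def __post_init__(self) -> None:
        for name in ("sd_intercept", "sd_slope_per_100d", "sd_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1.0 <= self.corr_intercept_slope <= 1.0:
            raise ValueError("correlation must lie in [-1, 1]")


@dataclass
class TrajectoryFit:
    """Fixed effects (per-100-days slope scale) and variance components
    for one phenotype."""

    phenotype: str
    beta0: Estimate
    beta1_sex: Estimate | None
    beta3_age: Estimate
    beta2_treatment: Estimate | None = None
    beta4_interaction: Estimate | None = None
    p_sex_interaction: float | None = None
    n_mice: int = 0
    n_observations: int = 0
    variance_components: VarianceComponents | None = None
    df_method: str = "residual"
    converged: bool = True
    singular: bool = False
    notes: list[str] = field(default_factory=list)
    treatment: str | None = None


def _as_frame(obj, to_frame) -> pd.DataFrame:
    if isinstance(obj, pd.DataFrame):
        return obj.copy()
    return to_frame(list(obj))


def _prepare(
    observations,
    cohort,
    phenotype: str,
    treatment: str | None,
    control_label: str,
    baseline_age_days: float,
) -> pd.DataFrame:
    obs = _as_frame(observations, observations_to_frame)
    coh = _as_frame(cohort, cohort_to_frame)
    df = obs[obs["phenotype"] == phenotype].merge(
        coh[["mouse_id", "sex", "treatment"]], on="mouse_id", how="inner"
    )
    if treatment is not None:
        if treatment == control_label:
            raise ValueError("treatment label must differ from the control label")
        df = df[df["treatment"].isin([control_label, treatment])].copy()
        df["treat"] = (df["treatment"] == treatment).astype(float)
    # repeated measures need >= 2 scans per animal
    counts = df.groupby("mouse_id")["value"].transform("size")
    df = df[counts >= 2].copy()
    if df.empty:
        raise ValueError(f"no usable observations for phenotype {phenotype!r}")
    df["male"] = (df["sex"] == "male").astype(float)
    df["t100"] = (df["age_days"] - baseline_age_days) / 100.0
    return df.reset_index(drop=True)


def _wald(params, bse, names, df_resid) -> dict[str, Estimate]:
    out = {}
    for name in names:
        b = float(params[name])
        se = float(bse[name])
        if se > 0 and np.isfinite(se):
            p = float(2.0 * stats.t.sf(abs(b) / se, df_resid))
        else:
            p = 0.0 if b != 0 else 1.0
        out[name] = Estimate(b, se, p)
    return out


def _ols_exact(df: pd.DataFrame, fixed: str) -> tuple[dict, float]:
    """OLS fit used for the degenerate zero-noise case; returns params and
    the residual mean square."""
    res = smf.ols(f"value ~ {fixed}", data=df).fit()
    return res, float(res.ssr / max(len(df), 1))


def _fit_ladder(df: pd.DataFrame, fixed: str, reml: bool):
    """Try free covariance, then independent random effects, then random
    intercept only.  Returns (result, level, notes)."""
    notes: list[str] = []
    attempts = [
        ("full", dict(re_formula="~t100")),
        ("independent", dict(re_formula="1", vc_formula={"slope": "0 + t100"})),
        ("intercept_only", dict(re_formula="1")),
    ]
    last = None
    for level, kw in attempts:
        model = smf.mixedlm(f"value ~ {fixed}", data=df, groups=df["mouse_id"], **kw)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(reml=reml, method="lbfgs", maxiter=200)
            except (np.linalg.LinAlgError, ValueError) as exc:
                notes.append(f"{level}: fit raised {exc!r}")
                continue
        last = (res, level)
        ok = bool(res.converged) and np.all(np.isfinite(res.bse_fe))
        if ok:
            if level != "full":
                notes.append(f"fell back to {level} random-effects structure")
            return res, level, notes
        notes.append(f"{level}: did not converge")
    if last is None:
        raise RuntimeError("mixed-model fit failed at every fallback level")
    res, level = last
    notes.append(f"returning non-converged {level} fit")
    return res, level, notes


def _variance_components(res, level: str) -> VarianceComponents:
    scale = float(res.scale)
    if level == "full":
        cov = np.asarray(res.cov_re)
        s0 = float(np.sqrt(max(cov[0, 0], 0.0)))
        s1 = float(np.sqrt(max(cov[1, 1], 0.0)))
        rho = float(cov[0, 1] / (s0 * s1)) if s0 > 0 and s1 > 0 else 0.0
        rho = float(np.clip(rho, -1.0, 1.0))
    elif level == "independent":
        s0 = float(np.sqrt(max(np.asarray(res.cov_re)[0, 0], 0.0)))
        s1 = float(np.sqrt(max(float(res.vcomp[0]), 0.0)))
        rho = 0.0
    else:
        s0 = float(np.sqrt(max(np.asarray(res.cov_re)[0, 0], 0.0)))
        s1, rho = 0.0, 0.0
    return VarianceComponents(s0, s1, rho, float(np.sqrt(max(scale, 0.0))))


def fit_trajectory(
    observations,
    cohort,
    phenotype: str,
    treatment: str | None = None,
    *,
    control_label: str = "control",
    baseline_age_days: float = BASELINE_AGE_DAYS,
    reml: bool = True,
    sex_interaction: bool = True,
) -> TrajectoryFit:
    """REML fit of the trajectory model for one phenotype.

    ``treatment=None`` fits the controls-only aging-rate model
    (value ~ sex + age); passing an arm label pools that arm with the
    controls and adds treatment main-effect and treatment x age terms, the
    latter being the intervention effect on the rate of change.  Mice with
    a single scan are dropped.  A sex x age interaction p-value is
    computed from an augmented refit when both sexes are present.
    """
    df = _prepare(observations, cohort, phenotype, treatment,
                  control_label, baseline_age_days)
    has_sex = df["male"].nunique() > 1
    terms = (["male"] if has_sex else []) + ["t100"]
    if treatment is not None:
        terms = (["male"] if has_sex else []) + ["treat", "t100", "treat:t100"]
    fixed = " + ".join(terms)
    n_fixed = len(terms) + 1
    df_resid = max(len(df) - n_fixed, 1)

    res, degenerate = None, False
    ols_res, msr = _ols_exact(df, fixed)
    rel = msr / max(float(np.var(df["value"])), 1e-300)
    if msr < 1e-18 or rel < 1e-24:
        # data lie exactly on the fixed-effect plane (zero-noise generator):
        # REML is singular, the OLS solution is exact
        degenerate = True
        params, bse = ols_res.params, ols_res.bse * 0.0
        level, notes = "degenerate", ["zero residual variance: exact OLS solution"]
        vc = VarianceComponents(0.0, 0.0, 0.0, 0.0)
    else:
        res, level, notes = _fit_ladder(df, fixed, reml)
        params, bse = res.fe_params, res.bse_fe
        vc = _variance_components(res, level)

    est = _wald(params, bse, ["Intercept"] + terms, df_resid)

    p_sex_int = None
    if sex_interaction and has_sex and not degenerate:
        aug = fixed + " + male:t100"
        try:
            res_sx, _, _ = _fit_ladder(df, aug, reml)
            w = _wald(res_sx.fe_params, res_sx.bse_fe, ["male:t100"],
                      max(len(df) - n_fixed - 1, 1))
            p_sex_int = w["male:t100"].p
        except RuntimeError:
            notes.append("sex-interaction refit failed")

    singular = (not degenerate) and (
        vc.sd_intercept == 0.0 or (level == "full" and abs(vc.corr_intercept_slope) >= 1.0)
    )
    fit = TrajectoryFit(
        phenotype=phenotype,
        beta0=est["Intercept"],
        beta1_sex=est.get("male"),
        beta3_age=est["t100"],
        beta2_treatment=est.get("treat"),
        beta4_interaction=est.get("treat:t100"),
        p_sex_interaction=p_sex_int,
        n_mice=int(df["mouse_id"].nunique()),
        n_observations=int(len(df)),
        variance_components=vc,
        df_method="residual",
        converged=degenerate or bool(res.converged),
        singular=singular,
        notes=notes,
        treatment=treatment,
    )
    return fit


def fit_trajectory_by_sex(observations, cohort, phenotype,
                          treatment: str | None = None, **kwargs
                          ) -> dict[str, TrajectoryFit]:
    """Sex-stratified variant: one fit per sex (sex term dropped)."""
    coh = _as_frame(cohort, cohort_to_frame)
    out: dict[str, TrajectoryFit] = {}
    for sex in ("female", "male"):
        ids = set(coh.loc[coh["sex"] == sex, "mouse_id"])
        obs = _as_frame(observations, observations_to_frame)
        sub = obs[obs["mouse_id"].isin(ids)]
        if sub.empty:
            continue
        out[sex] = fit_trajectory(sub, coh, phenotype, treatment,
                                  sex_interaction=False, **kwargs)
    return out


def drop_singletons_and_post_fracture(
    observations,
    fractures: list[tuple[str, float]],
    min_observations: int = 2,
):
    """Censoring rule for fractured femurs.

    Observations at or after a mouse's first fracture age are removed
    (the fracture-visit scan and everything after), then mice left with
    fewer than ``min_observations`` rows are dropped entirely.  Returns
    the same container type it was given (frame in, frame out).
    """
    was_frame = isinstance(observations, pd.DataFrame)
    df = _as_frame(observations, observations_to_frame)
    frac_age = {}
    for mouse_id, age in fractures:
        frac_age[mouse_id] = min(age, frac_age.get(mouse_id, np.inf))
    cut = df["mouse_id"].map(frac_age)
    keep = cut.isna() | (df["age_days"] < cut)
    df = df[keep]
    counts = df.groupby("mouse_id")["value"].transform("size")
    df = df[counts >= min_observations].reset_index(drop=True)
    if was_frame:
        return df
    return [ObservationRecord(r.mouse_id, r.phenotype, r.age_days, r.value)
            for r in df.itertuples()]


def annualize_rate(beta_per_100d: float) -> float:
    """Convert a per-100-days slope to change per year (x 365/100)."""
    return beta_per_100d * 365.0 / 100.0


def sparing_percent(control_slope: float, interaction_beta: float) -> float:
    """Intervention effect as a percentage of the control aging rate.

    100 * b4 / |b3_control|: positive when the interaction opposes the
    control slope (the treatment spares that fraction of the age-related
    change per unit time); 100 means the change is fully arrested.
    """
    if control_slope == 0:
        raise ValueError("sparing undefined for a zero control slope")
    return 100.0 * interaction_beta / abs(control_slope)


def qvalues(
    pvalues,
    *,
    pi0: float | None = None,
    lambdas: np.ndarray | None = None,
) -> np.ndarray:
    """Storey q-values.

    pi0 (the proportion of true nulls) is estimated from the tail
    proportions pi0(lam) = #{p > lam} / (m (1 - lam)) on a grid of lam,
    smoothed with a cubic spline and read off at the largest lam; pass
    ``pi0=1`` to recover Benjamini-Hochberg adjusted p-values exactly.
    q for the i-th smallest p is pi0 * min_{j >= i} (m p_(j) / j).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        if lambdas is None:
            lambdas = np.arange(0.05, 0.95 + 1e-9, 0.05)
        lambdas = np.asarray(lambdas, dtype=float)
        if m < 32 or p.max() < lambdas[0]:
            pi0_hat = 1.0  # too little information to estimate pi0
        else:
            tail = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
            try:
                spline = UnivariateSpline(lambdas, tail, k=3)
                pi0_hat = float(spline(lambdas[-1]))
            except Exception:
                pi0_hat = float(tail[-1])
            if not np.isfinite(pi0_hat) or pi0_hat <= 0.0:
                pi0_hat = 1.0
        pi0 = min(pi0_hat, 1.0)
    if not 0.0 < pi0 <= 1.0:
        raise ValueError("pi0 must lie in (0, 1]")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1] * pi0
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def trajectory_table(fits: list[TrajectoryFit], with_qvalues: bool = False
                     ) -> pd.DataFrame:
    """One row per phenotype: coefficient, SE, p, sex-interaction p.

    Control-only fits report the age slope (the aging-rate table layout);
    fits with a treatment arm report the treatment x age interaction (the
    treatment-effect table layout).  ``with_qvalues`` appends a Storey
    q-value column computed across the table's p-values.
    """
    rows = []
    for f in fits:
        eff = f.beta4_interaction if f.beta4_interaction is not None else f.beta3_age
        rows.append({
            "phenotype": f.phenotype,
            "n_mice": f.n_mice,
            "n_obs": f.n_observations,
            "beta_per_100d": eff.value,
            "se": eff.se,
            "p": eff.p,
            "p_sex_interaction": f.p_sex_interaction,
        })
    table = pd.DataFrame(
        rows, columns=["phenotype", "n_mice", "n_obs", "beta_per_100d",
                       "se", "p", "p_sex_interaction"])
    if with_qvalues and len(table):
        table["q"] = qvalues(table["p"].to_numpy())
    return table
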