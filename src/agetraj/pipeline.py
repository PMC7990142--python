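"""End-to-end orchestration: simulate -> censor -> fit -> tables -> power.

A RunConfig (usually loaded from YAML) describes the study design,
mortality, the generative trait specs and the power-grid request; a run
writes the trajectory, treatment-effect, fracture, survival and power
tables as CSV with a provenance header (config hash, seed, package
version) so that re-runs with the same seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (GenerativeTraitSpec, MortalitySpec, StudyDesignSpec,
                     cohort_to_frame, generate_cohort, observations_to_frame,
                     simulate_fractures, simulate_trait)
from .crosssec import fracture_frequency
from .longitudinal import (drop_singletons_and_post_fracture, fit_trajectory,
                           trajectory_table)
from .power import power_table
from .survival import fit_cox, survival_records

logger = logging.getLogger("agetraj")

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    seed: int = 0
    design: StudyDesignSpec = field(default_factory=StudyDesignSpec)
    mortality: MortalitySpec = field(default_factory=MortalitySpec)
    traits: list[GenerativeTraitSpec] = field(default_factory=list)
    power_effects: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 25.0, 50.0)
    power_visits: tuple[int, ...] = tuple(range(3, 10))
    power_spacing_days: float = 100.0

    def __post_init__(self) -> None:
        if not self.traits:
            raise ValueError("config must list at least one phenotype trait")

    def digest(self) -> str:
        payload = json.dumps(
            {
                "seed": self.seed,
                "design": vars(self.design) | {"treatments": list(self.design.treatments)},
                "mortality": vars(self.mortality),
                "traits": [vars(t) for t in self.traits],
                "power": [list(self.power_effects), list(self.power_visits),
                          self.power_spacing_days],
            },
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file (see examples/ for the schema)."""
    raw = yaml.safe_load(Path(path).read_text())
    design = StudyDesignSpec(**{**raw.get("design", {}),
                                **({"treatments": tuple(raw["design"]["treatments"])}
                                   if "treatments" in raw.get("design", {}) else {})})
    mortality = MortalitySpec(**raw.get("mortality", {}))
    traits = [GenerativeTraitSpec(**t) for t in raw.get("traits", [])]
    power = raw.get("power", {})
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        design=design,
        mortality=mortality,
        traits=traits,
        power_effects=tuple(power.get("effects", (5.0, 10.0, 15.0, 20.0, 25.0, 50.0))),
        power_visits=tuple(power.get("visits", range(3, 10))),
        power_spacing_days=float(power.get("spacing_days", 100.0)),
    )


def _write_csv(df: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    with path.open("w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, pd.DataFrame]:
    """Run the full analysis and write study-style tables under ``outdir``.

    Stages: cohort + trait simulation, fracture censoring, controls-only
    trajectory fits, per-arm treatment-effect fits, fracture incidence,
    Cox survival fits per arm, and the power grid from the first trait's
    fitted variance components.  Deterministic given the config seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    provenance = [
        f"agetraj {__version__}",
        f"seed={config.seed}",
        f"config_sha256={config.digest()}",
    ]
    results: dict[str, pd.DataFrame] = {}
    t0 = time.time()

    mice = generate_cohort(config.design, config.mortality, rng)
    logger.info("stage=simulate mice=%d", len(mice))
    cohort_df = cohort_to_frame(mice)
    results["cohort"] = cohort_df
    _write_csv(cohort_df, outdir / "cohort.csv", provenance)

    all_obs = []
    for spec in config.traits:
        all_obs.extend(simulate_trait(mice, spec, config.design, rng))
    obs_df = observations_to_frame(all_obs)
    fractures = simulate_fractures(mice, config.design, rng)
    n_before = len(obs_df)
    obs_df = drop_singletons_and_post_fracture(obs_df, fractures)
    logger.info("stage=censor fractures=%d obs_removed=%d",
                len(fractures), n_before - len(obs_df))
    results["observations"] = obs_df
    _write_csv(obs_df, outdir / "observations.csv", provenance)

    arms = [t for t in config.design.treatments if t != "control"]
    control_ids = set(cohort_df.loc[cohort_df["treatment"] == "control",
                                    "mouse_id"])
    obs_control = obs_df[obs_df["mouse_id"].isin(control_ids)]
    control_fits, effect_rows = [], []
    for spec in config.traits:
        try:
            fit = fit_trajectory(obs_control, cohort_df, spec.phenotype)
            control_fits.append(fit)
        except ValueError as exc:
            raise RuntimeError(f"stage=fit phenotype={spec.phenotype}: {exc}") from exc
        for arm in arms:
            tfit = fit_trajectory(obs_df, cohort_df, spec.phenotype, arm)
            row = trajectory_table([tfit]).iloc[0].to_dict()
            row["treatment"] = arm
            effect_rows.append(row)
    traj = trajectory_table(control_fits, with_qvalues=True)
    results["trajectories_control"] = traj
    _write_csv(traj, outdir / "trajectories_control.csv", provenance)
    if effect_rows:
        eff = pd.DataFrame(effect_rows)
        results["treatment_effects"] = eff
        _write_csv(eff, outdir / "treatment_effects.csv", provenance)
    logger.info("stage=fit phenotypes=%d arms=%d", len(config.traits), len(arms))

    if config.design.fracture_hazard_per_day > 0:
        k, n, pct = fracture_frequency(cohort_df, obs_df, fractures,
                                       config.design.fracture_min_age_days)
        frac = pd.DataFrame([{"fractures": k, "mice_at_risk": n, "percent": pct}])
        results["fracture_incidence"] = frac
        _write_csv(frac, outdir / "fracture_incidence.csv", provenance)

    surv_rows = []
    records = survival_records(cohort_df, config.design.max_age_days)
    for arm in arms:
        try:
            res = fit_cox(records, arm)
            eff = res.treatment
            surv_rows.append({"treatment": arm, "hr": eff.hr,
                              "ci_low": eff.ci_low, "ci_high": eff.ci_high,
                              "p": eff.p, "n": res.n, "events": res.n_events})
        except ValueError as exc:
            logger.warning("stage=survival arm=%s skipped: %s", arm, exc)
    if surv_rows:
        surv = pd.DataFrame(surv_rows)
        results["survival"] = surv
        _write_csv(surv, outdir / "survival.csv", provenance)

    lead = control_fits[0]
    if lead.variance_components is not None and lead.beta3_age.value != 0:
        ptab = power_table(
            lead.variance_components, lead.beta3_age.value,
            effects_percent=config.power_effects, visits=config.power_visits,
            visit_spacing_days=config.power_spacing_days,
        )
        grid = ptab.grid.reset_index()
        results["power_table"] = grid
        _write_csv(grid, outdir / f"power_{lead.phenotype}.csv", provenance)

    logger.info("stage=done elapsed=%.1fs", time.time() - t0)
    return results
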