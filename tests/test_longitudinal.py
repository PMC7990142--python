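"""Trajectory model fitting, censoring rules, rate arithmetic, q-values."""

import subprocess
import textwrap

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

import agetraj as at
from agetraj.cohort import make_mice


def simulate_fit(rng, n_female, n_male, spec, n_visits=4, treatment_arm=None,
                 spacing=91.0, **fit_kw):
    design = at.StudyDesignSpec(
        n_per_sex_per_arm=1,
        treatments=("control",) if treatment_arm is None else ("control", treatment_arm),
        visit_spacing_days=spacing,
        max_age_days=578.0 + (n_visits - 1) * spacing + 1.0,
        rolling_recruitment=False,
    )
    mice = make_mice(n_female, n_male)
    if treatment_arm:
        mice += make_mice(n_female, n_male, treatment_arm)
    obs = at.simulate_trait(mice, spec, design, rng)
    return at.fit_trajectory(obs, mice, spec.phenotype, treatment_arm, **fit_kw)


class TestFitTrajectory:
    def test_noiseless_data_recovers_coefficients_exactly(self, rng):
        spec = at.GenerativeTraitSpec(
            "BV.TV", beta0=55.0, beta1_sex=2.0, beta3_slope=-1.941,
            beta4_interaction={"HBX": 0.604})
        fit = simulate_fit(rng, 10, 10, spec, treatment_arm="HBX")
        assert fit.beta3_age.value == pytest.approx(-1.941, abs=1e-9)
        assert fit.beta4_interaction.value == pytest.approx(0.604, abs=1e-9)
        assert fit.beta1_sex.value == pytest.approx(2.0, abs=1e-9)
        assert fit.variance_components.sd_residual == 0.0

    def test_two_mouse_two_visit_slope_is_difference_quotient(self):
        # balanced grid: pooled slope = mean of per-mouse difference quotients
        mice = make_mice(2, 0)
        obs = [
            at.ObservationRecord(mice[0].mouse_id, "y", 578.0, 0.0),
            at.ObservationRecord(mice[0].mouse_id, "y", 678.0, 1.0),
            at.ObservationRecord(mice[1].mouse_id, "y", 578.0, 0.0),
            at.ObservationRecord(mice[1].mouse_id, "y", 678.0, 3.0),
        ]
        fit = at.fit_trajectory(obs, mice, "y", sex_interaction=False)
        assert fit.beta3_age.value == pytest.approx(2.0, abs=1e-6)

    def test_per_100_day_scale_is_pure_reparameterization(self, rng):
        # OLS slope per day x 100 equals the fitted per-100-days slope on
        # noiseless data
        spec = at.GenerativeTraitSpec("y", beta0=10.0, beta3_slope=-1.941)
        design = at.StudyDesignSpec(n_per_sex_per_arm=1, rolling_recruitment=False,
                                    max_age_days=578 + 3 * 91 + 1)
        mice = make_mice(3, 3)
        obs = at.observations_to_frame(at.simulate_trait(mice, spec, design, rng))
        t_days = obs["age_days"] - 578.0
        tc = t_days - t_days.mean()
        per_day = float((tc * (obs["value"] - obs["value"].mean())).sum()
                        / (tc ** 2).sum())
        assert per_day * 100.0 == pytest.approx(-1.941, rel=1e-12)

    def test_seeded_recovery_is_unbiased(self, rng, bone_spec):
        est = [simulate_fit(rng, 20, 20, bone_spec).beta3_age.value
               for _ in range(40)]
        mean, se = np.mean(est), np.std(est, ddof=1) / np.sqrt(len(est))
        assert abs(mean - (-1.941)) < 3 * se

    def test_variance_components_recovered_on_large_cohort(self, rng, bone_spec):
        fit = simulate_fit(rng, 250, 250, bone_spec, n_visits=6)
        vc = fit.variance_components
        assert vc.sd_intercept == pytest.approx(3.0, rel=0.10)
        assert vc.sd_slope_per_100d == pytest.approx(0.5, rel=0.10)
        assert vc.sd_residual == pytest.approx(1.5, rel=0.10)

    def test_sex_interaction_pvalue_detects_sex_specific_slope(self, rng):
        # males decline twice as fast -> small interaction p
        spec_m = at.GenerativeTraitSpec("y", beta0=50.0, beta3_slope=-2.0,
                                        sd_residual=0.5)
        spec_f = at.GenerativeTraitSpec("y", beta0=50.0, beta3_slope=-1.0,
                                        sd_residual=0.5)
        design = at.StudyDesignSpec(n_per_sex_per_arm=1, rolling_recruitment=False,
                                    max_age_days=578 + 3 * 91 + 1)
        males = make_mice(0, 30)
        females = make_mice(30, 0)
        obs = (at.simulate_trait(males, spec_m, design, rng)
               + at.simulate_trait(females, spec_f, design, rng))
        fit = at.fit_trajectory(obs, males + females, "y")
        assert fit.p_sex_interaction < 1e-4

    def test_sex_stratified_fits_cover_both_sexes(self, rng, bone_spec,
                                                  quarterly_design):
        mice = at.generate_cohort(quarterly_design, at.MortalitySpec.none(), rng)
        obs = at.simulate_trait(mice, bone_spec, quarterly_design, rng)
        fits = at.fit_trajectory_by_sex(obs, mice, "BV.TV")
        assert set(fits) == {"female", "male"}
        for fit in fits.values():
            assert abs(fit.beta3_age.value - (-1.941)) < 4 * fit.beta3_age.se

    def test_single_scan_mice_are_excluded(self, rng, bone_spec, quarterly_design):
        mice = at.generate_cohort(quarterly_design, at.MortalitySpec.none(), rng)
        obs = at.observations_to_frame(
            at.simulate_trait(mice, bone_spec, quarterly_design, rng))
        lone = obs[obs["mouse_id"] == mice[0].mouse_id].head(1)
        rest = obs[obs["mouse_id"] != mice[0].mouse_id]
        fit = at.fit_trajectory(
            __import__("pandas").concat([lone, rest]), mice, "BV.TV")
        assert fit.n_mice == len(mice) - 1


class TestAgainstLme4:
    def test_fixed_effects_match_lme4_reml(self, rng, bone_spec, tmp_path):
        """Independent oracle: the same REML fit in R/lme4."""
        design = at.StudyDesignSpec(n_per_sex_per_arm=1, rolling_recruitment=False,
                                    max_age_days=578 + 3 * 91 + 1)
        mice = make_mice(15, 15)
        obs = at.observations_to_frame(
            at.simulate_trait(mice, bone_spec, design, rng))
        coh = at.cohort_to_frame(mice)
        df = obs.merge(coh[["mouse_id", "sex"]], on="mouse_id")
        df["male"] = (df["sex"] == "male").astype(int)
        df["t100"] = (df["age_days"] - 578.0) / 100.0
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- lmer(value ~ male + t100 + (1 + t100 | mouse_id), data = d,
                      REML = TRUE)
            fe <- fixef(m)
            cat(sprintf("%.10f %.10f %.10f\\n", fe[1], fe[2], fe[3]))
        """))
        out = subprocess.run(["Rscript", str(rscript)], capture_output=True,
                             text=True, check=True)
        b0, b1, b3 = map(float, out.stdout.split())
        fit = at.fit_trajectory(obs, coh, "BV.TV", sex_interaction=False)
        assert fit.beta0.value == pytest.approx(b0, abs=5e-4)
        assert fit.beta1_sex.value == pytest.approx(b1, abs=5e-4)
        assert fit.beta3_age.value == pytest.approx(b3, abs=5e-4)


class TestCensoring:
    def make_obs(self, mouse_id, ages):
        return [at.ObservationRecord(mouse_id, "y", a, 1.0) for a in ages]

    def test_identity_without_fractures(self):
        obs = self.make_obs("m1", [578, 669]) + self.make_obs("m2", [578, 669, 760])
        assert at.drop_singletons_and_post_fracture(obs, []) == obs

    def test_fracture_visit_and_later_removed(self):
        ages = [578.0, 669.0, 760.0, 851.0, 942.0]
        obs = self.make_obs("m1", ages)
        kept = at.drop_singletons_and_post_fracture(obs, [("m1", 760.0)])
        assert [o.age_days for o in kept] == [578.0, 669.0]

    def test_hand_enumerated_ten_mouse_fixture_leaves_seven(self):
        # 10 mice: m0 single scan; m1 fractures at 2nd of 2 visits (left
        # with 1 -> dropped); m2 fractures at 3rd of 4 (left with 2 ->
        # kept); m3 fracture before first visit (dropped); m4-m9 clean
        obs = (self.make_obs("m0", [578])
               + self.make_obs("m1", [578, 669])
               + self.make_obs("m2", [578, 669, 760, 851])
               + self.make_obs("m3", [578, 669]))
        for k in range(4, 10):
            obs += self.make_obs(f"m{k}", [578, 669, 760])
        fractures = [("m1", 669.0), ("m2", 760.0), ("m3", 500.0)]
        kept = at.drop_singletons_and_post_fracture(obs, fractures)
        kept_ids = {o.mouse_id for o in kept}
        assert kept_ids == {"m2", "m4", "m5", "m6", "m7", "m8", "m9"}
        assert len(kept_ids) == 7


class TestRateArithmetic:
    @pytest.mark.parametrize(
        "beta,expected",
        [(-1.941, -7.08465), (0.0, 0.0), (-1.337, -4.88005)],
    )
    def test_annualize(self, beta, expected):
        assert at.annualize_rate(beta) == pytest.approx(expected, abs=1e-6)

    def test_annualized_magnitudes_match_reported_rates(self):
        # control loss 7.1 %/yr; under treatment (slope + interaction) 4.9 %/yr
        assert round(abs(at.annualize_rate(-1.941)), 1) == 7.1
        assert round(abs(at.annualize_rate(-1.941 + 0.604)), 1) == 4.9

    @pytest.mark.parametrize(
        "control,interaction,expected",
        [(-1.941, 0.604, 31.117), (-3.0, 0.0, 0.0), (-2.0, 2.0, 100.0)],
    )
    def test_sparing_percent(self, control, interaction, expected):
        assert at.sparing_percent(control, interaction) == pytest.approx(
            expected, abs=0.01)

    def test_sparing_undefined_for_zero_control_slope(self):
        with pytest.raises(ValueError):
            at.sparing_percent(0.0, 1.0)


class TestQValues:
    def test_equals_benjamini_hochberg_when_pi0_is_one(self, rng):
        p = rng.uniform(size=200) ** 1.5
        q = at.qvalues(p, pi0=1.0)
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, bh, atol=1e-12)

    def test_all_unit_pvalues_give_unit_qvalues(self):
        assert np.all(at.qvalues(np.ones(10)) == 1.0)

    def test_single_pvalue_with_pi0_one_is_itself(self):
        assert at.qvalues([0.031], pi0=1.0)[0] == pytest.approx(0.031)

    def test_monotone_in_p_rank_and_bounded(self, rng):
        p = np.concatenate([rng.uniform(size=300) ** 3, rng.uniform(size=300)])
        q = at.qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all((q >= 0) & (q <= 1))

    def test_pi0_estimate_shrinks_qvalues_under_signal(self, rng):
        # strong signal mixed with nulls: estimated pi0 < 1 so Storey q <= BH
        p = np.concatenate([rng.uniform(size=500) * 1e-3, rng.uniform(size=100)])
        q = at.qvalues(p)
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.all(q <= bh + 1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            at.qvalues([0.5, 1.5])


class TestTrajectoryTable:
    def test_control_and_treatment_layouts(self, rng, bone_spec):
        fit_c = simulate_fit(rng, 10, 10, bone_spec)
        spec_t = at.GenerativeTraitSpec(
            "BV.TV", beta0=55.0, beta3_slope=-1.941,
            beta4_interaction={"HBX": 0.604}, sd_residual=1.0)
        fit_t = simulate_fit(rng, 10, 10, spec_t, treatment_arm="HBX")
        table = at.trajectory_table([fit_c], with_qvalues=True)
        assert list(table.columns) == ["phenotype", "n_mice", "n_obs",
                                       "beta_per_100d", "se", "p",
                                       "p_sex_interaction", "q"]
        assert table.loc[0, "beta_per_100d"] == fit_c.beta3_age.value
        table_t = at.trajectory_table([fit_t])
        assert table_t.loc[0, "beta_per_100d"] == fit_t.beta4_interaction.value

    def test_empty_input_gives_empty_table(self):
        assert len(at.trajectory_table([])) == 0
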