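"""Cohort generation, trait/fracture/spine simulation, text round-trips."""

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter

import agetraj as at


def per_mouse_ols_slopes(obs, baseline=578.0):
    df = at.observations_to_frame(obs)
    df["t"] = (df["age_days"] - baseline) / 100.0
    slopes = {}
    for mid, g in df.groupby("mouse_id"):
        if len(g) < 2:
            continue
        tc = g["t"] - g["t"].mean()
        slopes[mid] = float((tc * (g["value"] - g["value"].mean())).sum()
                            / (tc ** 2).sum())
    return slopes


class TestGenerateCohort:
    def test_no_mortality_full_cells(self, rng):
        design = at.StudyDesignSpec(n_per_sex_per_arm=20)
        mice = at.generate_cohort(design, at.MortalitySpec.none(), rng)
        assert len(mice) == 40
        assert all(m.death_age_days is None and m.censored for m in mice)

    def test_exponential_death_fraction_matches_closed_form(self, rng):
        h, T = 1.0 / 400.0, 1095.0 - 578.0
        design = at.StudyDesignSpec(n_per_sex_per_arm=750,
                                    rolling_recruitment=False)
        mort = at.MortalitySpec(family="exponential", rate=h)
        mice = at.generate_cohort(design, mort, rng)
        dead = np.mean([m.death_age_days is not None for m in mice])
        expected = 1.0 - np.exp(-h * T)
        se = np.sqrt(expected * (1 - expected) / len(mice))
        assert abs(dead - expected) < 4 * se

    def test_rolling_recruitment_adds_late_entries_only_after_deaths(self, rng):
        design = at.StudyDesignSpec(n_per_sex_per_arm=20)
        mort = at.MortalitySpec(family="exponential", rate=1 / 250)
        mice = at.generate_cohort(design, mort, rng)
        late = [m for m in mice if m.enroll_age_days > design.enroll_age_days]
        assert len(mice) > 40 and late
        grid = set(np.round(at.visit_schedule(design), 6))
        assert all(round(m.enroll_age_days, 6) in grid for m in late)
        # no replacements without mortality
        assert len(at.generate_cohort(design, at.MortalitySpec.none(), rng)) == 40

    def test_kaplan_meier_agrees_with_analytic_survivor(self, rng):
        h = 1.0 / 350.0
        design = at.StudyDesignSpec(n_per_sex_per_arm=500, max_age_days=2500.0,
                                    rolling_recruitment=False)
        mice = at.generate_cohort(design, at.MortalitySpec("exponential", rate=h),
                                  rng)
        rec = at.survival_records(mice, design.max_age_days)
        t = rec["exit_age_days"] - rec["entry_age_days"]
        km = KaplanMeierFitter().fit(t, event_observed=rec["event"])
        ci = km.confidence_interval_survival_function_
        for q in (200.0, 400.0, 800.0):
            lo = float(ci.iloc[:, 0].asof(q))
            hi = float(ci.iloc[:, 1].asof(q))
            assert lo <= np.exp(-h * q) <= hi

    def test_fixed_seed_is_bit_reproducible(self, bone_spec, quarterly_design):
        def build(seed):
            rng = np.random.default_rng(seed)
            mort = at.MortalitySpec(family="exponential", rate=1 / 400)
            mice = at.generate_cohort(quarterly_design, mort, rng)
            obs = at.simulate_trait(mice, bone_spec, quarterly_design, rng)
            return at.cohort_to_frame(mice), at.observations_to_frame(obs)

        c1, o1 = build(7)
        c2, o2 = build(7)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(o1, o2)
        c3, _ = build(8)
        assert not c1.equals(c3)

    def test_observation_count_equals_visits_survived(self, rng, bone_spec):
        design = at.StudyDesignSpec(n_per_sex_per_arm=50)
        mort = at.MortalitySpec(family="exponential", rate=1 / 300)
        mice = at.generate_cohort(design, mort, rng)
        obs = at.simulate_trait(mice, bone_spec, design, rng)
        expected = sum(len(at.mouse_visit_ages(m, design)) for m in mice)
        assert len(obs) == expected


class TestSimulateTrait:
    def test_zero_noise_reproduces_seeded_slope_exactly(self, rng, quarterly_design):
        spec = at.GenerativeTraitSpec("BV.TV", beta0=55.0, beta1_sex=2.0,
                                      beta3_slope=-1.941)
        mice = at.generate_cohort(quarterly_design, at.MortalitySpec.none(), rng)
        obs = at.simulate_trait(mice, spec, quarterly_design, rng)
        slopes = per_mouse_ols_slopes(obs)
        assert len(slopes) == 40
        assert all(s == pytest.approx(-1.941, abs=1e-12) for s in slopes.values())

    def test_slope_dispersion_matches_sd_slope(self, rng):
        design = at.StudyDesignSpec(n_per_sex_per_arm=1500,
                                    rolling_recruitment=False,
                                    max_age_days=578 + 3 * 91 + 1)
        spec = at.GenerativeTraitSpec("y", beta0=0.0, beta3_slope=-1.0,
                                      sd_slope=0.5, sd_residual=0.0)
        mice = at.generate_cohort(design, at.MortalitySpec.none(), rng)
        slopes = np.array(list(per_mouse_ols_slopes(
            at.simulate_trait(mice, spec, design, rng)).values()))
        assert slopes.mean() == pytest.approx(-1.0, abs=0.03)
        assert slopes.std(ddof=1) == pytest.approx(0.5, rel=0.06)

    def test_constant_model_yields_constant_values(self, rng, quarterly_design):
        spec = at.GenerativeTraitSpec("y", beta0=7.0, beta1_sex=2.0)
        mice = at.generate_cohort(quarterly_design, at.MortalitySpec.none(), rng)
        df = at.observations_to_frame(
            at.simulate_trait(mice, spec, quarterly_design, rng))
        coh = at.cohort_to_frame(mice).set_index("mouse_id")
        male = df["mouse_id"].map(coh["sex"]).eq("male")
        assert np.allclose(df.loc[~male, "value"], 7.0)
        assert np.allclose(df.loc[male, "value"], 9.0)


class TestFractures:
    def test_zero_hazard_no_fractures(self, rng, quarterly_design):
        mice = at.generate_cohort(quarterly_design, at.MortalitySpec.none(), rng)
        assert at.simulate_fractures(mice, quarterly_design, rng) == []

    def test_fractures_only_after_minimum_age_and_at_most_one(self, rng):
        design = at.StudyDesignSpec(n_per_sex_per_arm=500,
                                    fracture_hazard_per_day=1e-3,
                                    rolling_recruitment=False)
        mice = at.generate_cohort(design, at.MortalitySpec.none(), rng)
        events = at.simulate_fractures(mice, design, rng)
        assert events
        ages = np.array([a for _, a in events])
        assert np.all(ages >= design.fracture_min_age_days)
        ids = [m for m, _ in events]
        assert len(ids) == len(set(ids))

    def test_event_fraction_matches_closed_form(self, rng):
        h = 2e-4
        design = at.StudyDesignSpec(n_per_sex_per_arm=5000,
                                    fracture_hazard_per_day=h,
                                    rolling_recruitment=False)
        mice = at.generate_cohort(design, at.MortalitySpec.none(), rng)
        events = at.simulate_fractures(mice, design, rng)
        exposure = design.max_age_days - design.fracture_min_age_days
        expected = 1.0 - np.exp(-h * exposure)
        frac = len(events) / len(mice)
        se = np.sqrt(expected * (1 - expected) / len(mice))
        assert abs(frac - expected) < 4 * se


class TestSpines:
    def test_roundtrip_through_scoring(self, rng, quarterly_design):
        trait = at.GenerativeTraitSpec("tortuosity", beta0=0.15,
                                       beta3_slope=0.01, sd_intercept=0.02,
                                       sd_slope=0.003, sd_residual=0.01)
        mice = at.generate_cohort(quarterly_design, at.MortalitySpec.none(), rng)
        spines = at.simulate_spines(mice[:10], quarterly_design, trait, rng)
        assert spines
        for s in spines:
            assert abs(at.compute_tortuosity(s.spine) - s.target_tortuosity) < 1e-6

    def test_out_of_range_target_rejected(self, rng, quarterly_design):
        trait = at.GenerativeTraitSpec("tortuosity", beta0=1.5)
        mice = at.generate_cohort(quarterly_design, at.MortalitySpec.none(), rng)
        with pytest.raises(ValueError, match=r"\[0, 1\)"):
            at.simulate_spines(mice[:2], quarterly_design, trait, rng)


class TestTextRoundTrips:
    def test_cohort_roundtrip_identity(self, rng, tmp_path):
        design = at.StudyDesignSpec(n_per_sex_per_arm=30)
        mort = at.MortalitySpec(family="exponential", rate=1 / 300)
        mice = at.generate_cohort(design, mort, rng)
        path = tmp_path / "cohort.csv"
        at.write_cohort(mice, path)
        assert at.read_cohort(path) == mice

    def test_full_study_size_cohort_roundtrips(self, rng, tmp_path):
        # the study enrolled 677 animals across arms
        mice = (at.make_mice(107, 110, "control")
                + at.make_mice(115, 115, "HBX")
                + at.make_mice(115, 115, "CQ"))
        assert len(mice) == 677
        path = tmp_path / "cohort.csv"
        at.write_cohort(mice, path)
        assert at.read_cohort(path) == mice

    def test_bad_sex_label_names_line(self, tmp_path):
        path = tmp_path / "cohort.csv"
        path.write_text(
            "mouse_id,sex,treatment,enroll_age_days,death_age_days,censored\n"
            "m1,female,control,578.0,,1\n"
            "m2,shrew,control,578.0,,1\n"
        )
        with pytest.raises(ValueError, match="line 3"):
            at.read_cohort(path)

    def test_observations_roundtrip(self, rng, tmp_path, bone_spec,
                                    quarterly_design):
        mice = at.generate_cohort(quarterly_design, at.MortalitySpec.none(), rng)
        obs = at.simulate_trait(mice, bone_spec, quarterly_design, rng)
        path = tmp_path / "obs.csv"
        at.write_observations(obs, path)
        assert at.read_observations(path) == obs

    def test_centerline_roundtrip_csv_and_json(self, tmp_path):
        spine = at.arc_centerline(0.2, n_points=40)
        for name in ("c.csv", "c.json"):
            path = tmp_path / name
            at.write_centerline(spine, path)
            back = at.read_centerline(path)
            assert np.allclose(back.points, spine.points)
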