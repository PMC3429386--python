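"""Synthetic-data generator: trajectories, observation noise model,
birth-history simulation, and the data-preparation rules."""

import numpy as np
import pandas as pd
import pytest

from childmort import (
    ScenarioConfig,
    SourceSpec,
    apply_vr_adjustment,
    flag_consistently_low_series,
    generate_birth_histories,
    generate_observations,
    generate_trajectory,
)
from conftest import make_config


class TestTrajectory:
    def test_constant_knots_give_constant_q5(self):
        traj = generate_trajectory(make_config(q5_start=0.1, q5_end=0.1))
        assert np.allclose(traj.q5, 0.1)

    def test_loglinear_decline_matches_closed_form(self):
        # 0.100 -> 0.025 over 20 years is a constant ARR of ln(4)/20
        traj = generate_trajectory(make_config(q5_start=0.100, q5_end=0.025))
        arr = np.log(4.0) / 20.0
        expected = 0.100 * np.exp(-arr * (traj.years - 1990))
        assert np.allclose(traj.q5, expected, rtol=1e-12)

    def test_conflict_spike_multiplies_only_its_years(self):
        base = generate_trajectory(make_config(q5_start=0.1, q5_end=0.1))
        spiked = generate_trajectory(
            make_config(q5_start=0.1, q5_end=0.1, conflict_spike=(2000, 2.0, 1))
        )
        i = list(spiked.years).index(2000)
        assert spiked.q5[i] == pytest.approx(0.2)
        mask = spiked.years != 2000
        assert np.allclose(spiked.q5[mask], base.q5[mask])

    def test_spike_pushing_q5_past_one_is_rejected(self):
        with pytest.raises(ValueError, match="spike"):
            generate_trajectory(
                make_config(q5_start=0.6, q5_end=0.6, conflict_spike=(2000, 2.0, 1))
            )

    def test_infant_split(self):
        traj = generate_trajectory(make_config())
        assert np.allclose(traj.q1, 0.7 * traj.q5)

    def test_config_invariants(self):
        with pytest.raises(ValueError, match="10 years"):
            ScenarioConfig("X", (1990, 1995), [(1990, -1.0), (1995, -1.0)])
        with pytest.raises(ValueError, match="increasing"):
            ScenarioConfig("X", (1990, 2010), [(2000, -1.0), (1995, -1.0)])


class TestObservations:
    def test_noise_free_unbiased_equals_truth(self, declining_trajectory):
        spec = SourceSpec("S", "survey_direct", 1.0, 0.0, range(1990, 2011), survey_year=2011)
        obs = generate_observations(declining_trajectory, [spec], seed=0)
        assert np.allclose(obs["value_per1000"], 1000 * declining_trajectory.q5)
        assert (obs["sampling_se"] == 0).all()

    def test_bias_only(self, declining_trajectory):
        spec = SourceSpec("V", "vr_incomplete", 0.8, 0.0, range(1990, 2011))
        obs = generate_observations(declining_trajectory, [spec], seed=0)
        assert np.allclose(obs["value_per1000"], 800 * declining_trajectory.q5)

    def test_lognormal_noise_model(self, declining_trajectory):
        # 10,000 replicate draws at one year: mean log within 3 SE of log truth
        cv = 0.05
        specs = [
            SourceSpec(f"S{k}", "survey_direct", 1.0, cv, [2000], survey_year=2000)
            for k in range(10_000)
        ]
        obs = generate_observations(declining_trajectory, specs, seed=11)
        logs = np.log(obs["value_per1000"].to_numpy())
        truth = np.log(1000 * declining_trajectory.q5_at([2000])[0])
        se = cv / np.sqrt(len(logs))
        assert abs(np.mean(logs) - truth) < 3 * se

    def test_empty_sources_give_empty_table(self, declining_trajectory):
        obs = generate_observations(declining_trajectory, [], seed=0)
        assert len(obs) == 0

    def test_fixed_seed_bit_identical(self, declining_trajectory):
        specs = [SourceSpec("S", "survey_direct", 1.0, 0.08, range(1990, 2005), survey_year=2005)]
        a = generate_observations(declining_trajectory, specs, seed=7)
        b = generate_observations(declining_trajectory, specs, seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestBirthHistories:
    def test_negligible_hazard_no_deaths(self):
        traj = generate_trajectory(make_config(q5_start=1e-9, q5_end=1e-9))
        bh = generate_birth_histories(traj, 200, 0.2, 2005, seed=1)
        assert bh["death_age_months"].isna().all()

    def test_empirical_mortality_matches_schedule(self):
        # constant q5 = 0.2; fully exposed cohorts should die before 60
        # months at that rate, within 3 Monte Carlo SE
        traj = generate_trajectory(make_config(q5_start=0.2, q5_end=0.2, year_range=(1980, 2010)))
        bh = generate_birth_histories(traj, 20_000, 0.3, 2010, seed=5, reproductive_window=20)
        full = bh[bh["birth_year_decimal"] <= 2005.0 - 1e-9]
        died = full["death_age_months"].notna() & (full["death_age_months"] < 60)
        p = died.mean()
        se = np.sqrt(0.2 * 0.8 / len(full))
        assert abs(p - 0.2) < 3 * se

    def test_early_survey_censors_everyone_before_age_five(self):
        traj = generate_trajectory(make_config(q5_start=0.3, q5_end=0.3))
        bh = generate_birth_histories(traj, 500, 0.5, 1993, seed=2, reproductive_window=3)
        ages_at_survey = (bh["survey_year"] - bh["birth_year_decimal"]) * 12
        assert (ages_at_survey < 60).all()

    def test_deterministic_for_fixed_seed(self, declining_trajectory):
        a = generate_birth_histories(declining_trajectory, 300, 0.2, 2005, seed=9)
        b = generate_birth_histories(declining_trajectory, 300, 0.2, 2005, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_bad_fertility_rejected(self, declining_trajectory):
        with pytest.raises(ValueError, match="fertility"):
            generate_birth_histories(declining_trajectory, 10, 0.0, 2005, seed=0)


def vr_records(values, years=None, source_id="VR", source_type="vr_complete"):
    years = years if years is not None else range(2000, 2000 + len(values))
    return pd.DataFrame(
        {
            "country_id": "X",
            "ref_time": [float(y) for y in years],
            "value_per1000": values,
            "source_id": source_id,
            "source_type": source_type,
            "sampling_se": [v * 0.02 for v in values],
            "excluded": False,
            "duplicate_of": None,
        }
    )


class TestVrAdjustment:
    def test_twenty_percent_adjustment(self):
        out = apply_vr_adjustment(vr_records([100.0]), 1.2)
        assert out["value_per1000"].iloc[0] == pytest.approx(120.0)

    def test_identity_factor(self):
        recs = vr_records([50.0, 60.0])
        out = apply_vr_adjustment(recs, 1.0)
        assert np.allclose(out["value_per1000"], recs["value_per1000"])

    def test_elementwise_and_se_scaling(self):
        out = apply_vr_adjustment(vr_records([50.0, 60.0, 70.0]), 1.1)
        assert np.allclose(out["value_per1000"], [55.0, 66.0, 77.0])
        assert np.allclose(out["sampling_se"], out["value_per1000"] * 0.02)

    def test_multiplicative_composition(self):
        recs = vr_records([50.0, 60.0])
        once = apply_vr_adjustment(recs, 1.1 * 1.2)
        twice = apply_vr_adjustment(apply_vr_adjustment(recs, 1.1), 1.2)
        assert np.allclose(once["value_per1000"], twice["value_per1000"])

    def test_non_vr_rejected(self):
        recs = vr_records([100.0], source_type="survey_direct")
        with pytest.raises(ValueError, match="non-VR"):
            apply_vr_adjustment(recs, 1.1)


class TestConsistentlyLowFlag:
    def two_sources(self, low_everywhere=True):
        a = vr_records([40, 42, 44, 46, 48], source_id="A", source_type="survey_direct")
        b_vals = [50, 52, 54, 56, 58] if low_everywhere else [50, 52, 43, 56, 58]
        b = vr_records(b_vals, source_id="B", source_type="survey_direct")
        return pd.concat([a, b], ignore_index=True)

    def test_below_at_all_overlaps_excluded(self):
        out = flag_consistently_low_series(self.two_sources(True))
        assert out.loc[out["source_id"] == "A", "excluded"].all()
        assert not out.loc[out["source_id"] == "B", "excluded"].any()

    def test_below_at_most_but_not_all_retained(self):
        out = flag_consistently_low_series(self.two_sources(False))
        assert not out.loc[out["source_id"] == "A", "excluded"].any()

    def test_three_sources_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        frames = []
        offsets = {"A": -10.0, "B": 0.0, "C": 2.0}  # A below both everywhere
        for sid, off in offsets.items():
            vals = 60 + off + rng.uniform(0, 1, 5)
            frames.append(vr_records(list(vals), source_id=sid, source_type="survey_direct"))
        records = pd.concat(frames, ignore_index=True)
        out = flag_consistently_low_series(records, window=1.0)
        # oracle: exhaustive pairwise comparison over all year pairs
        expected_flags = {}
        for sid in offsets:
            own = records[records["source_id"] == sid]
            others = records[records["source_id"] != sid]
            pairs = [
                (r.value_per1000, o.value_per1000)
                for r in own.itertuples()
                for o in others.itertuples()
                if abs(r.ref_time - o.ref_time) <= 1.0
            ]
            expected_flags[sid] = bool(pairs) and all(v < o for v, o in pairs)
        assert expected_flags == {"A": True, "B": False, "C": False}
        for sid, flag in expected_flags.items():
            assert out.loc[out["source_id"] == sid, "excluded"].all() == flag

    def test_no_overlap_warns_and_leaves_unflagged(self):
        a = vr_records([40], years=[1990], source_id="A", source_type="survey_direct")
        b = vr_records([50], years=[2005], source_id="B", source_type="survey_direct")
        with pytest.warns(UserWarning, match="no overlap"):
            out = flag_consistently_low_series(pd.concat([a, b], ignore_index=True))
        assert not out["excluded"].any()

    def test_order_independent_with_vr_adjustment(self):
        vr = vr_records([40.0, 42.0, 44.0, 46.0, 48.0], source_id="VR", source_type="vr_incomplete")
        survey = vr_records([50.0, 52.0, 54.0, 56.0, 58.0], source_id="S", source_type="survey_direct")
        # adjust-then-flag vs flag-then-adjust; the modest factor preserves
        # every pairwise ordering, so the flags and values must agree
        both = pd.concat([vr, survey], ignore_index=True)
        flag_first = flag_consistently_low_series(both)
        flag_first.loc[flag_first["source_id"] == "VR", ["value_per1000", "sampling_se"]] = (
            apply_vr_adjustment(vr, 1.1)[["value_per1000", "sampling_se"]].to_numpy()
        )
        adjusted = pd.concat([apply_vr_adjustment(vr, 1.1), survey], ignore_index=True)
        adjust_first = flag_consistently_low_series(adjusted)
        pd.testing.assert_frame_equal(
            flag_first.sort_values(["source_id", "ref_time"]).reset_index(drop=True),
            adjust_first.sort_values(["source_id", "ref_time"]).reset_index(drop=True),
        )
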