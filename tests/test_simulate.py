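"""Synthetic-cohort generator: determinism, calibration, fixtures."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import robscore as rs
from robscore.exceptions import ValidationError
from robscore.simulate import (
    SimulationConfig,
    TruncNorm,
    draw_day1,
    make_track_fixture,
    simulate_cohort,
)
from robscore.survival import build_valid_cohort, cumulative_mortality


class TestDeterminism:
    def test_same_seed_same_cohort(self):
        a = simulate_cohort(SimulationConfig(seed=42))
        b = simulate_cohort(SimulationConfig(seed=42))
        pd.testing.assert_frame_equal(a.assessments, b.assessments)
        pd.testing.assert_frame_equal(a.autopsy, b.autopsy)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        assert [(x.animal_id, x.events) for x in a.ledger] == [
            (x.animal_id, x.events) for x in b.ledger
        ]

    def test_different_seeds_differ(self):
        a = simulate_cohort(SimulationConfig(seed=1))
        b = simulate_cohort(SimulationConfig(seed=2))
        assert not a.assessments["ot_distance"].equals(b.assessments["ot_distance"])


class TestTruncNorm:
    def test_infeasible_truncation_raises(self):
        with pytest.raises(ValidationError, match="mass"):
            TruncNorm(5.0, 1.0, 5.0, 5.0).sample(np.random.default_rng(0))

    def test_range_must_contain_location(self):
        with pytest.raises(ValidationError):
            TruncNorm(100.0, 10.0, 0.0, 50.0)

    def test_theoretical_moments_reflect_truncation(self):
        # Asymmetric truncation shifts the realised mean above the location.
        tn = TruncNorm(38.0, 60.0, 0.0, 154.0)
        assert tn.mean() > tn.loc
        assert tn.std() < tn.scale


class TestCalibration:
    def test_day1_means_recovered_within_3_se(self):
        """Sample means at n=1000 per class sit within 3 SE of the truncated
        distributions' theoretical means."""
        rng = np.random.default_rng(2024)
        config = SimulationConfig()
        n = 1000
        for cls in ("severe", "moderate", "mild"):
            dists = config.day1[cls]
            draws = np.array([draw_day1(dists, rng) for _ in range(n)])
            for j, tn in enumerate((dists.rotarod, dists.openfield, dists.bwl)):
                se = tn.std() / np.sqrt(n)
                assert abs(draws[:, j].mean() - tn.mean()) <= 3 * se, (cls, j)

    def test_severe_class_total_mortality_by_day_four(self):
        """With the default severe hazards (certain death on day 4), every
        severe-only replicate reaches 100% cumulative mortality by day 4."""
        rates = []
        for seed in range(500):
            config = SimulationConfig(
                n_per_class={"severe": 6}, n_sham=0, autopsy_plan=(), seed=seed
            )
            sim = simulate_cohort(config)
            _, scored, _ = build_valid_cohort(sim.ledger)
            rates.append(cumulative_mortality(scored, 4).percent)
        assert abs(np.mean(rates) - 100.0) <= 5.0

    def test_truth_vs_rob_class_agreement_floor(self):
        """Day-1 ROB assignment recovers the latent class for a majority of
        animals under the default class distributions (calibration sanity
        check; the 0.5 floor is a design choice, not an empirical claim)."""
        config = SimulationConfig(
            n_per_class={"severe": 500, "moderate": 500, "mild": 500}, n_sham=0, seed=9
        )
        sim = simulate_cohort(config)
        agree = (sim.truth["true_class"] == sim.truth["rob_severity"]).mean()
        assert agree >= 0.5


class TestLedgerConsistency:
    def test_every_animal_appears_once_with_consistent_history(self):
        sim = simulate_cohort(SimulationConfig(seed=5))
        ids = sim.ledger.ids()
        assert len(ids) == len(set(ids)) == 29 + 3
        sim.ledger.validate()
        for a in sim.ledger:
            assert a.terminal_event is not None  # everyone dies or is harvested
        # No assessment after an animal's terminal day.
        terminal = {a.animal_id: a.terminal_event.day for a in sim.ledger}
        for _, row in sim.assessments.iterrows():
            assert row["day"] <= terminal[row["animal_id"]]

    def test_assessment_trials_average_to_claimed_mean(self):
        sim = simulate_cohort(SimulationConfig(seed=5))
        trials = sim.assessments[["rt1", "rt2", "rt3"]].to_numpy()
        assert np.all(trials >= 0) and np.all(trials <= 300)

    def test_severity_from_truth_gives_configured_group_sizes(self):
        sim = simulate_cohort(SimulationConfig(seed=5, n_sham=0, severity_from="truth"))
        sizes = {
            s: sum(1 for a in sim.ledger if a.severity == s)
            for s in ("severe", "moderate", "mild")
        }
        assert sizes == {"severe": 6, "moderate": 18, "mild": 5}


class TestTrackFixture:
    def test_zero_target_is_stationary(self):
        track = make_track_fixture(0.0, seed=1)
        assert rs.path_distance(rs.sample_keyframes(track, 0)) == 0.0

    def test_target_distance_hit_exactly(self):
        track = make_track_fixture(643.0, seed=1)
        d = rs.path_distance(rs.sample_keyframes(track, 0))
        assert abs(d - 643.0) <= 1e-6

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValidationError, match="key-frame window"):
            make_track_fixture(100.0, n_frames=100)

    def test_simulated_tracks_reproduce_assessment_distances(self):
        config = SimulationConfig(
            n_per_class={"mild": 2}, n_sham=0, make_tracks=True, seed=3
        )
        sim = simulate_cohort(config)
        for (animal_id, day), sub in sim.tracks.groupby(["animal_id", "day"]):
            track = rs.TrackedPath(
                sub["frame"].to_numpy(int), sub[["x", "y"]].to_numpy(float)
            )
            d = rs.path_distance(rs.sample_keyframes(track, 0))
            claimed = sim.assessments.query(
                "animal_id == @animal_id and day == @day"
            )["ot_distance"].item()
            assert d == pytest.approx(claimed, abs=1e-6)


class TestConfig:
    def test_dict_round_trip(self):
        config = SimulationConfig(seed=11)
        assert SimulationConfig.from_dict(config.to_dict()) == config

    def test_invalid_hazard_rejected(self):
        config = dataclasses.replace(
            SimulationConfig(), hazards={"severe": {2: 1.5}, "moderate": {}, "mild": {}}
        )
        with pytest.raises(ValidationError, match="hazard"):
            config.validate()
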