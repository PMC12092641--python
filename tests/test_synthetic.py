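"""Determinism, structure and steering of the synthetic study generator."""

import numpy as np
import pandas as pd
import pytest

import pignet as pn
from pignet.cognition import detect_pass, profiles_from_frame
from pignet.events import involvement_seconds
from pignet.networks import nonlittermate_counts
from pignet.synthetic import (
    EffectConfig,
    _frame_to_event_list,
    _sdt_locations,
    damaging_received_seconds,
    expected_lesion_mean,
    generate_events,
    generate_pen,
    generate_pig_trials,
    generate_study,
    space_allowance_m2,
)


class TestPens:
    def test_same_seed_same_roster(self):
        a = generate_pen("pen1", np.random.default_rng(1))
        b = generate_pen("pen1", np.random.default_rng(1))
        assert a.pigs == b.pigs

    def test_roster_structure(self):
        for seed in range(20):
            pen = generate_pen("p", np.random.default_rng(seed))
            assert 12 <= pen.n_pigs <= 14
            sexes = [p.sex for p in pen.pigs]
            assert abs(sexes.count("M") - sexes.count("F")) <= 1
            assert all(p.weight_kg > 0 for p in pen.pigs)
            litter_sizes = pd.Series([p.litter_id for p in pen.pigs]).value_counts()
            assert litter_sizes.max() <= 4
            for pig in pen.pigs:
                assert 6 <= pen.n_nonlittermates(pig) <= 14

    def test_single_pig_pen_rejected(self):
        with pytest.raises(ValueError, match="2 pigs"):
            generate_pen("p", np.random.default_rng(0), n_pigs=1)

    def test_weight_distribution_matches_study_conditions(self):
        weights, within = [], []
        for seed in range(40):
            pen = generate_pen("p", np.random.default_rng(seed))
            w = [p.weight_kg for p in pen.pigs]
            weights += w
            within.append(np.std(w, ddof=1))
        assert np.mean(weights) == pytest.approx(62.4, abs=2.5)
        assert np.std(weights) == pytest.approx(7.2, abs=1.5)
        assert 3.0 < np.mean(within) < 7.0  # within-pen spread kept low

    def test_nonlittermate_mean_near_study_value(self):
        counts = []
        for seed in range(30):
            study = generate_study(n_pens=2, seed=seed)
            counts += list(nonlittermate_counts(study.roster).values())
        assert np.mean(counts) == pytest.approx(10.8, abs=1.0)


def test_space_allowance_of_average_group():
    assert round(space_allowance_m2(14), 2) == 1.02
    with pytest.raises(ValueError):
        space_allowance_m2(0)


class TestTrials:
    def test_perfect_learner_passes_in_minimum_trials(self):
        rows = generate_pig_trials(
            "p", np.random.default_rng(0), p_learn=1.0, onset_trial=1
        )
        flags = [
            (r["decision"] == "go") == (r["location"] == "positive") for r in rows
        ]
        assert detect_pass(flags) == (True, 12)

    def test_never_more_than_two_consecutive_negatives(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            locs = _sdt_locations(rng, 36)
            run = 0
            for loc in locs:
                run = run + 1 if loc == "negative" else 0
                assert run <= 2

    def test_trial_phases_have_correct_lengths(self, small_study):
        lengths = small_study.trials.groupby(["pig", "phase"])["trial"].agg(
            ["max", "count"]
        )
        for (_, phase), row in lengths.iterrows():
            expected = 36 if phase == "SDT" else 20
            assert row["max"] == expected and row["count"] == expected

    def test_chance_learner_pass_rate_matches_window_scan_probability(self):
        # Monte-Carlo pass rate at p = 0.5 vs an independent dynamic-
        # programming computation over window states
        rng = np.random.default_rng(11)
        n = 2000
        passes = 0
        for _ in range(n):
            rows = generate_pig_trials("p", rng, p_learn=0.5, onset_trial=1)
            flags = [
                (r["decision"] == "go") == (r["location"] == "positive")
                for r in rows
            ]
            passes += detect_pass(flags)[0]
        p_dp = _pass_probability_dp(n_trials=36, window=12, min_correct=10, p=0.5)
        se = np.sqrt(p_dp * (1 - p_dp) / n)
        assert passes / n == pytest.approx(p_dp, abs=4 * se)

    def test_cohort_median_speed_near_study_median(self, small_study):
        profiles = profiles_from_frame(small_study.trials)
        speeds = [p.trials_to_pass for p in profiles if p.sdt_passed]
        assert 13 <= np.median(speeds) <= 19  # anchored at the 17-trial split


def _pass_probability_dp(n_trials, window, min_correct, p):
    """P(any window of `window` trials holds >= min_correct correct),
    by exact enumeration over the last (window-1) outcomes."""
    from itertools import product

    states = {}
    for bits in product((0, 1), repeat=window - 1):
        states[bits] = 0.0
    # start: build up the first window-1 trials
    frontier = {(): 1.0}
    for _ in range(window - 1):
        nxt = {}
        for hist, prob in frontier.items():
            for b in (0, 1):
                nxt[hist + (b,)] = nxt.get(hist + (b,), 0.0) + prob * (
                    p if b else 1 - p
                )
        frontier = nxt
    alive = dict(frontier)
    passed = 0.0
    for _ in range(n_trials - window + 1):
        nxt = {}
        for hist, prob in alive.items():
            for b in (0, 1):
                pr = prob * (p if b else 1 - p)
                if sum(hist) + b >= min_correct:
                    passed += pr
                else:
                    nxt_hist = hist[1:] + (b,)
                    nxt[nxt_hist] = nxt.get(nxt_hist, 0.0) + pr
        alive = nxt
    return passed


class TestEvents:
    def test_zero_rates_give_empty_stream(self):
        pen = generate_pen("p", np.random.default_rng(0))
        effects = EffectConfig(
            nondamaging_rate=0.0, damaging_rate=0.0, fight_rate=0.0,
            littermate_rate=0.0,
        )
        assert generate_events(pen, effects, np.random.default_rng(1)) == []

    def test_streams_are_valid_pipeline_inputs(self, small_study, eth):
        from pignet.events import frame_to_events

        for pen_id, sub in small_study.events.groupby("pen_id"):
            events = frame_to_events(sub.drop(columns=["pen_id"]), eth)
            assert events  # parsed without validation errors

    def test_involvement_median_within_calibration_band(self, small_study):
        inv = involvement_seconds(_frame_to_event_list(small_study.events))
        assert 300 <= np.median(list(inv.values())) <= 1200

    def test_littermate_dyads_get_no_damaging_aggression(self, small_study, eth):
        litter_of = dict(
            zip(small_study.roster["pig_id"], small_study.roster["litter_id"])
        )
        for e in _frame_to_event_list(small_study.events):
            if e.receiver and litter_of[e.actor] == litter_of[e.receiver]:
                assert not eth.is_damaging(e.code)
                assert eth.category(e.code) != "mutual_fight"

    def test_male_rate_multiplier_raises_male_aggression(self):
        male_excess = []
        effects = EffectConfig(male_rate_multiplier=2.0)
        for seed in range(15):
            rng = np.random.default_rng(seed)
            pen = generate_pen("p", rng)
            events = generate_events(pen, effects, rng)
            acted = pd.Series([e.actor for e in events]).value_counts()
            sex = {p.pig_id: p.sex for p in pen.pigs}
            male = np.mean([acted.get(p, 0) for p in sex if sex[p] == "M"])
            female = np.mean([acted.get(p, 0) for p in sex if sex[p] == "F"])
            male_excess.append(male - female)
        assert np.mean(male_excess) > 0

    def test_event_times_respect_observation_window(self, small_study_events):
        assert all(e.t_end <= 18_000 for e in small_study_events)


class TestLesions:
    def test_baseline_only_without_received_aggression(self):
        eff = EffectConfig()
        assert expected_lesion_mean(0.0, "anterior", eff) == pytest.approx(1.5)

    def test_expected_excess_is_linear_in_received_seconds(self):
        eff = EffectConfig()
        base = expected_lesion_mean(0.0, "central", eff)
        one = expected_lesion_mean(100.0, "central", eff) - base
        two = expected_lesion_mean(200.0, "central", eff) - base
        assert two == pytest.approx(2 * one)

    def test_anterior_exceeds_posterior_on_average(self, small_study):
        at_24h = small_study.lesions.query("timepoint == '24h'")
        means = at_24h.groupby("region")["count"].mean()
        assert means["anterior"] > means["central"] > means["posterior"]

    def test_received_seconds_accumulate_by_category(self, eth):
        from pignet.events import BehaviourEvent

        events = [
            BehaviourEvent(1.0, "A", "B", "single_bite"),
            BehaviourEvent(5.0, "A", "B", "bully", 20.0),
            BehaviourEvent(50.0, "A", "B", "fight", 30.0),
        ]
        rec = damaging_received_seconds(events)
        assert rec["B"] == pytest.approx(1.0 + 20.0 + 30.0)
        assert rec["A"] == pytest.approx(30.0)  # fights injure both


class TestStudy:
    def test_full_determinism_under_fixed_seed(self):
        a = generate_study(n_pens=2, seed=42)
        b = generate_study(n_pens=2, seed=42)
        pd.testing.assert_frame_equal(a.roster, b.roster)
        pd.testing.assert_frame_equal(a.events, b.events)
        pd.testing.assert_frame_equal(a.trials, b.trials)
        pd.testing.assert_frame_equal(a.lesions, b.lesions)
        assert a.reversal_passers == b.reversal_passers

    def test_different_seeds_differ(self):
        a = generate_study(n_pens=2, seed=1)
        b = generate_study(n_pens=2, seed=2)
        assert not a.events.equals(b.events)

    def test_ground_truth_passers_match_scored_profiles(self, small_study):
        profiles = profiles_from_frame(small_study.trials)
        scored = {p.pig for p in profiles if p.reversal_passed is True}
        assert scored == small_study.reversal_passers
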