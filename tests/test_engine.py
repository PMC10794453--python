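"""Trial state machine: epochs, contingencies, timing, protocols."""

import numpy as np
import pytest

from finloop import default_arena
from finloop.engine import (ColourAssignment, Command, ProtocolConfig,
                            SessionState, assign_trial_contingency,
                            init_session, pretraining_step, protocol_preset,
                            render_screen, run_session, sample_iti, step)
from finloop.tracking import TrackSample


@pytest.fixture(scope="module")
def arena():
    return default_arena()


def mk_sample(t, start=False, left=False, right=False, counts=None, idx=0):
    occ = {"start": start, "choice_left": left, "choice_right": right}
    return TrackSample(frame_index=idx, t=t, centroid=(10.0, 10.0),
                       luminance=0.0, roi_occupancy=occ,
                       roi_counts=counts or {})


def fixed_timing_config(**overrides):
    kw = dict(phase="acquisition", iti_min_s=2.0, iti_max_s=2.0,
              outcome_delay_s=1.0, n_trials=24, session_timeout_s=1e6,
              rewarded_side_rule="fixed_left")
    kw.update(overrides)
    return ProtocolConfig(**kw)


def oracle_feed(n_trials, dt=0.25, choose_left=True):
    """Closed-form feed for a fixed-ITI (2 s), 1 s outcome-delay session.

    The subject sits in the start zone except for a single-frame excursion
    into a choice zone 0.5 s after each stimulus onset; with the fixed
    timing, trial k's choice frame falls at 3.75 k + 2.75 s exactly.
    """
    period = 3.75
    t, idx = dt, 0
    while t <= n_trials * period + 10:
        k = int(t // period)
        phase_t = round(t - k * period, 6)
        choice_frame = abs(phase_t - 2.75) < dt / 2
        yield mk_sample(t, start=not choice_frame,
                        left=choice_frame and choose_left,
                        right=choice_frame and not choose_left, idx=idx)
        t = round(t + dt, 6)
        idx += 1


class TestSampleIti:
    def test_degenerate_uniform(self):
        rng = np.random.default_rng(0)
        assert sample_iti(rng, 30, 30) == 30.0

    def test_within_bounds(self):
        rng = np.random.default_rng(1)
        draws = [sample_iti(rng, 20, 40) for _ in range(1000)]
        assert min(draws) >= 20 and max(draws) <= 40

    def test_mean_of_uniform(self):
        rng = np.random.default_rng(2)
        draws = [sample_iti(rng, 20, 40) for _ in range(10_000)]
        assert np.mean(draws) == pytest.approx(30.0, abs=0.2)

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            sample_iti(np.random.default_rng(0), 10, 5)


class TestContingencyAssignment:
    def test_fixed_rules(self):
        rng = np.random.default_rng(0)
        cfg_l = fixed_timing_config(rewarded_side_rule="fixed_left")
        cfg_r = fixed_timing_config(rewarded_side_rule="fixed_right")
        for k in range(5):
            assert assign_trial_contingency(cfg_l, k, rng) == "left"
            assert assign_trial_contingency(cfg_r, k, rng) == "right"

    def test_swapped_is_complement_of_acquisition_side(self):
        rng = np.random.default_rng(0)
        for acq_side, rev_side in (("left", "right"), ("right", "left")):
            cfg = fixed_timing_config(
                phase="reversal", rewarded_side_rule="swapped",
                contingency=ColourAssignment(s_plus_side=acq_side))
            for k in range(10):
                assert assign_trial_contingency(cfg, k, rng) == rev_side

    def test_random_per_trial_is_binomial_half(self):
        rng = np.random.default_rng(3)
        cfg = fixed_timing_config(phase="colour_random",
                                  rewarded_side_rule="random_per_trial")
        sides = [assign_trial_contingency(cfg, k, rng) for k in range(10_000)]
        frac_left = sides.count("left") / len(sides)
        assert 0.48 <= frac_left <= 0.52


class TestStepTransitions:
    def test_iti_ignores_occupancy(self, arena):
        cfg = fixed_timing_config()
        rng = np.random.default_rng(0)
        state, _ = init_session(cfg, arena, rng)
        # mid-ITI samples with every possible occupancy: no transition
        for t in (0.5, 1.0, 1.5):
            state, cmds = step(state, mk_sample(t, start=True, left=True),
                               cfg, arena, rng)
            assert state.epoch == "ITI"
            assert not any(c.kind == "dispense_pellet" for c in cmds)

    def test_trial_available_then_start_entry_triggers_stimuli(self, arena):
        cfg = fixed_timing_config()
        rng = np.random.default_rng(0)
        state, _ = init_session(cfg, arena, rng)
        state, cmds = step(state, mk_sample(2.0), cfg, arena, rng)
        assert state.epoch == "TRIAL_AVAILABLE"
        state, cmds = step(state, mk_sample(2.25, start=True), cfg, arena, rng)
        assert state.epoch == "STIMULUS_ON"
        screens = [c.payload for c in cmds if c.kind == "set_screen"]
        assert len(screens) == 1 and len(screens[0].stimuli) == 2
        names = [c.payload.name for c in cmds if c.kind == "log_event"]
        assert names == ["START_ENTRY", "STIM_ON"]

    def test_correct_choice_dispenses_after_exact_delay(self, arena):
        cfg = fixed_timing_config(outcome_delay_s=5.0)
        rng = np.random.default_rng(0)
        state, _ = init_session(cfg, arena, rng)
        state, _ = step(state, mk_sample(2.0), cfg, arena, rng)
        state, _ = step(state, mk_sample(2.25, start=True), cfg, arena, rng)
        state, cmds = step(state, mk_sample(3.0, left=True), cfg, arena, rng)
        assert state.epoch == "OUTCOME_DELAY"
        # no dispense for 5 s after the choice
        for t in np.arange(3.25, 7.99, 0.25):
            state, cmds = step(state, mk_sample(float(t)), cfg, arena, rng)
            assert not any(c.kind == "dispense_pellet" for c in cmds)
        state, cmds = step(state, mk_sample(8.0), cfg, arena, rng)
        dispense = [c for c in cmds if c.kind == "dispense_pellet"]
        assert len(dispense) == 1 and dispense[0].payload == "left"
        assert any(c.kind == "log_event" and c.payload.name == "REWARD"
                   for c in cmds)

    def test_incorrect_choice_logs_omission_no_dispense(self, arena):
        cfg = fixed_timing_config()
        rng = np.random.default_rng(0)
        state, _ = init_session(cfg, arena, rng)
        state, _ = step(state, mk_sample(2.0), cfg, arena, rng)
        state, _ = step(state, mk_sample(2.25, start=True), cfg, arena, rng)
        state, cmds = step(state, mk_sample(2.5, right=True), cfg, arena, rng)
        choice = [c.payload for c in cmds if c.kind == "log_event"][0]
        assert choice.name == "CHOICE_RIGHT" and choice.code == 0
        state, cmds = step(state, mk_sample(3.5), cfg, arena, rng)
        assert not any(c.kind == "dispense_pellet" for c in cmds)
        assert any(c.kind == "log_event" and c.payload.name == "OMISSION"
                   for c in cmds)

    def test_choice_latching_ignores_later_entries(self, arena):
        cfg = fixed_timing_config()
        rng = np.random.default_rng(0)
        state, _ = init_session(cfg, arena, rng)
        state, _ = step(state, mk_sample(2.0), cfg, arena, rng)
        state, _ = step(state, mk_sample(2.25, start=True), cfg, arena, rng)
        state, _ = step(state, mk_sample(2.5, right=True), cfg, arena, rng)
        assert state.pending_choice == "right"
        state, _ = step(state, mk_sample(2.75, left=True), cfg, arena, rng)
        assert state.pending_choice == "right"

    def test_double_entry_tie_break_by_pixel_sum_then_left(self, arena):
        cfg = fixed_timing_config()
        rng = np.random.default_rng(0)
        state, _ = init_session(cfg, arena, rng)
        state, _ = step(state, mk_sample(2.0), cfg, arena, rng)
        state, _ = step(state, mk_sample(2.25, start=True), cfg, arena, rng)
        both = mk_sample(2.5, left=True, right=True,
                         counts={"choice_left": 40, "choice_right": 90})
        state, _ = step(state, both, cfg, arena, rng)
        assert state.pending_choice == "right"

    def test_non_monotonic_timestamp_rejected(self, arena):
        cfg = fixed_timing_config()
        rng = np.random.default_rng(0)
        state, _ = init_session(cfg, arena, rng)
        state, _ = step(state, mk_sample(1.0), cfg, arena, rng)
        with pytest.raises(ValueError, match="non-monotonic"):
            step(state, mk_sample(0.5), cfg, arena, rng)


class TestRenderScreen:
    def test_iti_black_no_stimuli(self, arena):
        cfg = fixed_timing_config()
        st_ = SessionState("ITI", 0, 0.0, 2.0, "left", None, 0.0)
        spec = render_screen(st_, cfg, arena.screen)
        assert spec.background_level == 0
        assert spec.stimuli == ()
        assert spec.epoch_indicator_level == 0

    def test_stimulus_layout_follows_s_plus_side(self, arena):
        cfg = fixed_timing_config(
            contingency=ColourAssignment("red", "blue", "right"),
            rewarded_side_rule="fixed_right")
        st_ = SessionState("STIMULUS_ON", 0, 0.0, 2.0, "right", None, 0.0)
        spec = render_screen(st_, cfg, arena.screen)
        by_side = {s.side: s for s in spec.stimuli}
        assert by_side["right"].colour == "red"
        assert by_side["left"].colour == "blue"
        # mirror-symmetric centres
        assert by_side["left"].centre_cm[0] + by_side["right"].centre_cm[0] \
            == pytest.approx(arena.tank.width_cm)

    def test_post_choice_indicator_above_available(self, arena):
        cfg = fixed_timing_config()
        avail = render_screen(
            SessionState("TRIAL_AVAILABLE", 0, 0.0, 2.0, "left", None, 0.0),
            cfg, arena.screen)
        post = render_screen(
            SessionState("OUTCOME_DELAY", 0, 0.0, 2.0, "left", "left", 0.0),
            cfg, arena.screen)
        assert post.epoch_indicator_level > avail.epoch_indicator_level


class TestPretraining:
    def test_choice_zone_training_even_split(self, arena):
        cfg = protocol_preset("choice_zone_training", rng_seed=4)
        rng = np.random.default_rng(cfg.rng_seed)
        state, _ = init_session(cfg, arena, rng)
        sched = state.signalled_schedule
        assert len(sched) == 12
        assert sched.count("left") == 6 and sched.count("right") == 6

    def test_choice_zone_training_iti_bounds(self):
        cfg = protocol_preset("choice_zone_training")
        assert (cfg.iti_min_s, cfg.iti_max_s) == (5.0, 10.0)
        rng = np.random.default_rng(0)
        draws = [sample_iti(rng, cfg.iti_min_s, cfg.iti_max_s)
                 for _ in range(100)]
        assert min(draws) >= 5 and max(draws) <= 10

    def test_choice_zone_training_skips_start_gate(self, arena):
        cfg = protocol_preset("choice_zone_training", rng_seed=1)
        rng = np.random.default_rng(1)
        state, _ = init_session(cfg, arena, rng)
        state, cmds = pretraining_step(state, mk_sample(10.0), cfg, arena, rng)
        assert state.epoch == "STIMULUS_ON"
        screens = [c.payload for c in cmds if c.kind == "set_screen"]
        assert len(screens[0].stimuli) == 1
        assert screens[0].stimuli[0].shape == "noise_rect"

    def test_unsignalled_zone_entry_ignored(self, arena):
        cfg = protocol_preset("choice_zone_training", rng_seed=1)
        rng = np.random.default_rng(1)
        state, _ = init_session(cfg, arena, rng)
        state, _ = pretraining_step(state, mk_sample(10.0), cfg, arena, rng)
        signalled = state.current_s_plus_side
        other = "right" if signalled == "left" else "left"
        wrong = mk_sample(10.5, left=(other == "left"),
                          right=(other == "right"))
        state, _ = pretraining_step(state, wrong, cfg, arena, rng)
        assert state.epoch == "STIMULUS_ON"  # still waiting
        good = mk_sample(11.0, left=(signalled == "left"),
                         right=(signalled == "right"))
        state, _ = pretraining_step(state, good, cfg, arena, rng)
        assert state.epoch == "OUTCOME_DELAY"

    def test_start_position_variant_gates_on_back_region(self, arena):
        from finloop.arena import ArenaModel, pretraining_start_roi
        rois = dict(arena.rois)
        rois["start"] = pretraining_start_roi(arena.tank, "back_half")
        arena_a = ArenaModel(tank=arena.tank, rois=rois, camera=arena.camera,
                             screen=arena.screen)
        cfg = protocol_preset("start_position_training_A", rng_seed=2)
        rng = np.random.default_rng(2)
        state, _ = init_session(cfg, arena_a, rng)
        state, _ = pretraining_step(state, mk_sample(40.0), cfg, arena_a, rng)
        assert state.epoch == "TRIAL_AVAILABLE"
        # front-half occupancy (start=False) does not trigger
        state, _ = pretraining_step(state, mk_sample(40.5, left=True),
                                    cfg, arena_a, rng)
        assert state.epoch == "TRIAL_AVAILABLE"
        state, _ = pretraining_step(state, mk_sample(41.0, start=True),
                                    cfg, arena_a, rng)
        assert state.epoch == "STIMULUS_ON"

    def test_main_phase_rejected(self, arena):
        cfg = fixed_timing_config()
        rng = np.random.default_rng(0)
        state, _ = init_session(cfg, arena, rng)
        with pytest.raises(ValueError, match="not a pre-training"):
            pretraining_step(state, mk_sample(0.5), cfg, arena, rng)


class TestRunSession:
    def test_perfect_oracle_feed_earns_all_rewards(self, arena):
        cfg = fixed_timing_config(n_trials=24)
        events, tracking, truncated = run_session(
            cfg, arena, oracle_feed(24))
        assert not truncated
        assert sum(e.name == "REWARD" for e in events) == 24
        assert sum(e.name == "OMISSION" for e in events) == 0

    def test_event_log_reconstructs_trial_blocks(self, arena):
        cfg = fixed_timing_config(n_trials=6)
        events, _, _ = run_session(cfg, arena, oracle_feed(6))
        for name, expect in (("ITI_START", 6), ("TRIAL_AVAILABLE", 6),
                             ("STIM_ON", 6), ("REWARD", 6),
                             ("SESSION_END", 1)):
            assert sum(e.name == name for e in events) == expect

    def test_outcome_time_is_response_time_plus_delay(self, arena):
        cfg = fixed_timing_config(n_trials=4)
        events, _, _ = run_session(cfg, arena, oracle_feed(4))
        dt = 0.25
        stims = [e.t for e in events if e.name == "STIM_ON"]
        choices = [e.t for e in events if e.name.startswith("CHOICE")]
        outcomes = [e.t for e in events if e.name in ("REWARD", "OMISSION")]
        for s, c, o in zip(stims, choices, outcomes):
            rt = c - s
            assert abs((o - s) - (rt + cfg.outcome_delay_s)) <= dt + 1e-9

    def test_never_starting_ends_at_timeout_with_zero_trials(self, arena):
        cfg = fixed_timing_config(n_trials=24, session_timeout_s=30.0)
        feed = (mk_sample(0.25 * i) for i in range(1, 2000))
        events, _, truncated = run_session(cfg, arena, feed)
        assert not truncated
        assert sum(e.name in ("REWARD", "OMISSION") for e in events) == 0
        end = [e for e in events if e.name == "SESSION_END"]
        assert len(end) == 1 and end[0].code == 0

    def test_feed_exhaustion_marks_truncated(self, arena):
        cfg = fixed_timing_config(n_trials=24)
        feed = (mk_sample(0.25 * i) for i in range(1, 20))
        events, _, truncated = run_session(cfg, arena, feed)
        assert truncated
        assert events[-1].name == "SESSION_TRUNCATED"

    def test_one_outcome_per_trial_and_no_iti_dispense(self, arena):
        """Conservation invariants on a mixed-choice session."""
        cfg = fixed_timing_config(n_trials=10)
        events, _, _ = run_session(cfg, arena, oracle_feed(10,
                                                           choose_left=False))
        outcomes = [e for e in events if e.name in ("REWARD", "OMISSION")]
        assert len(outcomes) == 10
        assert all(e.name == "OMISSION" for e in outcomes)  # S+ is left

    def test_determinism_identical_config_and_feed(self, arena):
        cfg = fixed_timing_config(n_trials=5, iti_min_s=1.0, iti_max_s=3.0,
                                  rng_seed=9)
        ev1, _, _ = run_session(cfg, arena, oracle_feed(8))
        ev2, _, _ = run_session(cfg, arena, oracle_feed(8))
        assert ev1 == ev2
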