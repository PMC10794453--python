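"""Closed-loop trial controller.

The task is a two-alternative forced choice run in a Y-maze tank: every trial
starts with an inter-trial interval (ITI, black screen) during which
behaviour has no programmed consequences; ITI offset turns the screen grey,
signalling that the subject may self-initiate a trial by entering the start
zone; presence in the start zone triggers stimulus onset (two coloured
circles, S+ and S-); the first subsequent entry into a choice zone latches
the choice, and after a fixed outcome delay a food pellet is dispensed on the
S+ side (or omitted for S-), after which a fresh ITI begins.  Outside these
receptive epochs the subject's position has no effect.

The controller is a pure step function over per-frame tracking samples: each
step consumes one :class:`~finloop.tracking.TrackSample` and returns the next
session state plus a list of :class:`Command` objects (screen updates,
pellet-dispense requests and log events) for the rig — or, in this package,
for the virtual tank.

Pre-training protocols are variants of the same machine: choice-zone training
drops the start-zone gate and signals one side with a white-noise rectangle;
start-position training re-introduces the gate with progressively smaller
start zones (back half, back quarter, final 10x10 cm square).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal

import numpy as np

from .arena import ArenaModel, ScreenLayout
from .io_logs import EventRecord, TrackRecord
from .tracking import TrackSample

__all__ = [
    "Phase",
    "ColourAssignment",
    "ProtocolConfig",
    "SessionState",
    "Command",
    "StimulusSpec",
    "ScreenSpec",
    "sample_iti",
    "assign_trial_contingency",
    "render_screen",
    "init_session",
    "step",
    "pretraining_step",
    "run_session",
    "protocol_preset",
]

Phase = Literal[
    "acclimatisation",
    "choice_zone_training",
    "start_position_training_A",
    "start_position_training_B",
    "start_position_training_C",
    "acquisition",
    "reversal",
    "colour_random",
]

PRETRAINING_PHASES = (
    "acclimatisation", "choice_zone_training",
    "start_position_training_A", "start_position_training_B",
    "start_position_training_C",
)

COLOURS = ("red", "green", "blue", "white")


@dataclass(frozen=True)
class ColourAssignment:
    """Per-subject stimulus/reward contingency.

    ``s_plus_side`` is the rewarded side during phases with a fixed side
    (acquisition; its complement is used under the ``swapped`` rule in
    reversal).
    """

    s_plus_colour: str = "red"
    s_minus_colour: str = "green"
    s_plus_side: Literal["left", "right"] = "left"

    def __post_init__(self) -> None:
        if self.s_plus_colour == self.s_minus_colour:
            raise ValueError("S+ and S- colours must differ")
        for c in (self.s_plus_colour, self.s_minus_colour):
            if c not in COLOURS:
                raise ValueError(f"unknown stimulus colour {c!r}")


@dataclass(frozen=True)
class ProtocolConfig:
    phase: Phase = "acquisition"
    iti_min_s: float = 20.0
    iti_max_s: float = 40.0
    outcome_delay_s: float = 5.0
    n_trials: int = 24
    session_timeout_s: float = 3600.0
    contingency: ColourAssignment = field(default_factory=ColourAssignment)
    rewarded_side_rule: Literal["fixed_left", "fixed_right", "swapped",
                                "random_per_trial"] = "fixed_left"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.iti_min_s <= self.iti_max_s):
            raise ValueError("need 0 < iti_min_s <= iti_max_s")
        if self.n_trials <= 0 and self.phase != "acclimatisation":
            raise ValueError("n_trials must be > 0")
        if self.outcome_delay_s < 0:
            raise ValueError("outcome_delay_s must be >= 0")


def protocol_preset(phase: Phase,
                    contingency: ColourAssignment | None = None,
                    rng_seed: int = 0, **overrides) -> ProtocolConfig:
    """Standard session parameters for each protocol phase.

    Main-experiment sessions run 24 trials with ITI ~ U[20, 40] s and a 5 s
    outcome delay; choice-zone training runs 12 trials with ITI ~ U[5, 10] s
    and a 30 min session limit; start-position training runs 12 trials with
    the main ITI and a 1 h limit.
    """
    contingency = contingency or ColourAssignment()
    base = dict(phase=phase, contingency=contingency, rng_seed=rng_seed)
    if phase == "acclimatisation":
        base.update(n_trials=1, session_timeout_s=600.0)
    elif phase == "choice_zone_training":
        base.update(iti_min_s=5.0, iti_max_s=10.0, n_trials=12,
                    session_timeout_s=1800.0)
    elif phase.startswith("start_position_training"):
        base.update(n_trials=12, session_timeout_s=3600.0)
    elif phase == "acquisition":
        base.update(rewarded_side_rule="fixed_left"
                    if contingency.s_plus_side == "left" else "fixed_right")
    elif phase == "reversal":
        base.update(rewarded_side_rule="swapped")
    elif phase == "colour_random":
        base.update(rewarded_side_rule="random_per_trial")
    else:
        raise ValueError(f"unknown phase {phase!r}")
    base.update(overrides)
    return ProtocolConfig(**base)


@dataclass(frozen=True)
class StimulusSpec:
    shape: Literal["circle", "noise_rect"]
    colour: str  # circle colour, or "noise" for the rectangle
    side: Literal["left", "right"]
    centre_cm: tuple[float, float]  # (from left screen edge, from bottom)
    size_cm: tuple[float, float]


@dataclass(frozen=True)
class ScreenSpec:
    background_level: int
    stimuli: tuple[StimulusSpec, ...]
    epoch_indicator_level: int


Epoch = Literal["ITI", "TRIAL_AVAILABLE", "STIMULUS_ON", "OUTCOME_DELAY",
                "ENDED"]


@dataclass(frozen=True)
class SessionState:
    epoch: Epoch
    trial_index: int
    epoch_entry_t: float
    current_iti_s: float
    current_s_plus_side: Literal["left", "right"]
    pending_choice: Literal["left", "right"] | None
    clock: float
    # pre-training: fixed per-session schedule of signalled sides
    signalled_schedule: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.pending_choice is not None and self.epoch != "OUTCOME_DELAY":
            raise ValueError("pending_choice set outside OUTCOME_DELAY")


@dataclass(frozen=True)
class Command:
    kind: Literal["set_screen", "dispense_pellet", "log_event", "end_session"]
    payload: object = None


def sample_iti(rng: np.random.Generator, iti_min_s: float,
               iti_max_s: float) -> float:
    """Draw one ITI duration from U[iti_min_s, iti_max_s]."""
    if iti_min_s > iti_max_s:
        raise ValueError("iti_min_s must be <= iti_max_s")
    return float(rng.uniform(iti_min_s, iti_max_s))


def assign_trial_contingency(config: ProtocolConfig, trial_index: int,
                             rng: np.random.Generator) -> str:
    """The S+ side for a given trial under the configured side rule."""
    rule = config.rewarded_side_rule
    if rule == "fixed_left":
        return "left"
    if rule == "fixed_right":
        return "right"
    if rule == "swapped":
        return "right" if config.contingency.s_plus_side == "left" else "left"
    if rule == "random_per_trial":
        return "left" if rng.random() < 0.5 else "right"
    raise ValueError(f"unknown rewarded_side_rule {rule!r}")


def _circle_centres(layout: ScreenLayout, tank_width_cm: float
                    ) -> dict[str, tuple[float, float]]:
    off = layout.circle_side_offset_cm
    bot = layout.circle_bottom_offset_cm
    return {"left": (off, bot), "right": (tank_width_cm - off, bot)}


def render_screen(state: SessionState, config: ProtocolConfig,
                  layout: ScreenLayout,
                  tank_width_cm: float = 30.0) -> ScreenSpec:
    """Screen contents for the current epoch.

    ITI is a black screen with no stimuli; trial availability is signalled by
    a plain grey screen; stimulus onset adds the two circles (S+ on the
    current rewarded side) or, in pre-training, a single white-noise
    rectangle on the signalled side; the post-choice epoch raises the
    indicator strip to its high level.
    """
    levels = layout.epoch_levels
    if state.epoch in ("ITI", "ENDED"):
        return ScreenSpec(0, (), levels["ITI"])
    if state.epoch == "TRIAL_AVAILABLE":
        return ScreenSpec(layout.background_level, (),
                          levels["TRIAL_AVAILABLE"])
    if state.epoch == "STIMULUS_ON":
        centres = _circle_centres(layout, tank_width_cm)
        if config.phase in PRETRAINING_PHASES:
            side = state.current_s_plus_side
            stim = StimulusSpec(
                "noise_rect", "noise", side, centres[side],
                (layout.noise_rect_w_cm, layout.noise_rect_h_cm))
            stimuli = (stim,)
        else:
            a = config.contingency
            plus, minus = state.current_s_plus_side, (
                "right" if state.current_s_plus_side == "left" else "left")
            d = layout.circle_diameter_cm
            stimuli = (
                StimulusSpec("circle", a.s_plus_colour, plus, centres[plus],
                             (d, d)),
                StimulusSpec("circle", a.s_minus_colour, minus, centres[minus],
                             (d, d)),
            )
        return ScreenSpec(layout.background_level, stimuli,
                          levels["STIMULUS_ON"])
    # OUTCOME_DELAY
    return ScreenSpec(layout.background_level, (), levels["OUTCOME_DELAY"])


def _signalled_schedule(config: ProtocolConfig,
                        rng: np.random.Generator) -> tuple[str, ...]:
    """Evenly split left/right signals in random order (pre-training)."""
    n = config.n_trials
    sides = ["left"] * ((n + 1) // 2) + ["right"] * (n // 2)
    return tuple(np.array(sides)[rng.permutation(n)])


def _first_side(config: ProtocolConfig, schedule: tuple[str, ...],
                rng: np.random.Generator) -> str:
    if config.phase in PRETRAINING_PHASES and config.phase != "acclimatisation":
        return schedule[0]
    return assign_trial_contingency(config, 0, rng)


def init_session(config: ProtocolConfig, arena: ArenaModel,
                 rng: np.random.Generator
                 ) -> tuple[SessionState, list[Command]]:
    """Build the initial state (first ITI already sampled) and commands."""
    schedule = ()
    if config.phase in ("choice_zone_training", "start_position_training_A",
                        "start_position_training_B",
                        "start_position_training_C"):
        schedule = _signalled_schedule(config, rng)
    iti = sample_iti(rng, config.iti_min_s, config.iti_max_s)
    state = SessionState(
        epoch="ITI", trial_index=0, epoch_entry_t=0.0, current_iti_s=iti,
        current_s_plus_side=_first_side(config, schedule, rng),
        pending_choice=None, clock=0.0, signalled_schedule=schedule)
    cmds = [
        Command("log_event", EventRecord("ITI_START", 0.0, 0)),
        Command("set_screen",
                render_screen(state, config, arena.screen,
                              arena.tank.width_cm)),
    ]
    return state, cmds


def _choice_from_sample(sample: TrackSample, state: SessionState,
                        config: ProtocolConfig) -> str | None:
    """Which choice zone, if any, registers on this frame.

    During pre-training only the signalled zone is receptive; entry into the
    other zone is ignored.  A simultaneous double-entry (geometrically
    near-impossible with the divider) is broken by the larger in-zone pixel
    sum, then left.
    """
    occ_l = sample.roi_occupancy.get("choice_left", False)
    occ_r = sample.roi_occupancy.get("choice_right", False)
    if config.phase in PRETRAINING_PHASES:
        sig = state.current_s_plus_side
        occ = occ_l if sig == "left" else occ_r
        return sig if occ else None
    if occ_l and occ_r:
        nl = sample.roi_counts.get("choice_left", 0)
        nr = sample.roi_counts.get("choice_right", 0)
        return "right" if nr > nl else "left"
    if occ_l:
        return "left"
    if occ_r:
        return "right"
    return None


def step(state: SessionState, sample: TrackSample, config: ProtocolConfig,
         arena: ArenaModel,
         rng: np.random.Generator) -> tuple[SessionState, list[Command]]:
    """Advance the session by one tracking sample.

    Returns the successor state and the commands emitted on this frame.
    Raises ``ValueError`` if the sample's timestamp precedes the session
    clock.
    """
    if sample.t < state.clock:
        raise ValueError(f"non-monotonic timestamp {sample.t} < {state.clock}")
    t = sample.t
    cmds: list[Command] = []
    st = replace(state, clock=t)

    def screen(s: SessionState) -> Command:
        return Command("set_screen",
                       render_screen(s, config, arena.screen,
                                     arena.tank.width_cm))

    def log(name: str, code: int) -> Command:
        return Command("log_event", EventRecord(name, round(t, 3), code))

    if st.epoch == "ENDED":
        return st, cmds

    # session-level time limit applies in every epoch
    if t >= config.session_timeout_s:
        st = replace(st, epoch="ENDED", pending_choice=None, epoch_entry_t=t)
        cmds += [log("SESSION_END", st.trial_index), Command("end_session")]
        return st, cmds

    if st.epoch == "ITI":
        # behaviour has no consequences; only the timer matters
        if t - st.epoch_entry_t >= st.current_iti_s:
            if config.phase == "choice_zone_training":
                st = replace(st, epoch="STIMULUS_ON", epoch_entry_t=t)
                cmds += [log("STIM_ON", st.trial_index), screen(st)]
            else:
                st = replace(st, epoch="TRIAL_AVAILABLE", epoch_entry_t=t)
                cmds += [log("TRIAL_AVAILABLE", st.trial_index), screen(st)]
        return st, cmds

    if st.epoch == "TRIAL_AVAILABLE":
        if config.phase == "acclimatisation":
            return st, cmds  # free exploration; no contingencies
        if sample.roi_occupancy.get("start", False):
            st = replace(st, epoch="STIMULUS_ON", epoch_entry_t=t)
            cmds += [log("START_ENTRY", st.trial_index),
                     log("STIM_ON", st.trial_index), screen(st)]
        return st, cmds

    if st.epoch == "STIMULUS_ON":
        chosen = _choice_from_sample(sample, st, config)
        if chosen is not None:
            correct = chosen == st.current_s_plus_side
            st = replace(st, epoch="OUTCOME_DELAY", epoch_entry_t=t,
                         pending_choice=chosen)
            name = "CHOICE_LEFT" if chosen == "left" else "CHOICE_RIGHT"
            cmds += [log(name, int(correct)), screen(st)]
        return st, cmds

    # OUTCOME_DELAY
    if t - st.epoch_entry_t >= config.outcome_delay_s:
        chosen = st.pending_choice
        correct = chosen == st.current_s_plus_side
        trial = st.trial_index
        if correct:
            cmds += [Command("dispense_pellet", chosen),
                     log("REWARD", trial)]
        else:
            cmds.append(log("OMISSION", trial))
        next_trial = trial + 1
        if next_trial >= config.n_trials:
            st = replace(st, epoch="ENDED", trial_index=next_trial,
                         pending_choice=None, epoch_entry_t=t)
            cmds += [log("SESSION_END", next_trial), Command("end_session")]
        else:
            if st.signalled_schedule:
                side = st.signalled_schedule[next_trial]
            else:
                side = assign_trial_contingency(config, next_trial, rng)
            st = replace(st, epoch="ITI", trial_index=next_trial,
                         pending_choice=None, epoch_entry_t=t,
                         current_iti_s=sample_iti(rng, config.iti_min_s,
                                                  config.iti_max_s),
                         current_s_plus_side=side)
            cmds += [log("ITI_START", next_trial), screen(st)]
    return st, cmds


def pretraining_step(state: SessionState, sample: TrackSample,
                     config: ProtocolConfig, arena: ArenaModel,
                     rng: np.random.Generator
                     ) -> tuple[SessionState, list[Command]]:
    """`step` restricted to the pre-training phases."""
    if config.phase not in PRETRAINING_PHASES:
        raise ValueError(f"{config.phase!r} is not a pre-training phase")
    return step(state, sample, config, arena, rng)


def run_session(config: ProtocolConfig, arena: ArenaModel,
                tracker_feed: Iterable[TrackSample],
                rng: np.random.Generator | None = None,
                ) -> tuple[list[EventRecord], list[TrackRecord], bool]:
    """Drive the state machine over a pre-tracked sample stream.

    Returns the complete event list, the per-frame tracking records, and a
    flag marking whether the feed was exhausted before the session ended
    (such sessions are logged with a final SESSION_TRUNCATED event).
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    state, cmds = init_session(config, arena, rng)
    events = [c.payload for c in cmds if c.kind == "log_event"]
    tracking: list[TrackRecord] = []
    last_t = 0.0
    prev_t = -np.inf
    for sample in tracker_feed:
        if sample.t <= prev_t:
            raise ValueError("tracker feed timestamps must strictly increase")
        prev_t = sample.t
        x, y = (sample.centroid if sample.centroid is not None
                else (None, None))
        tracking.append(TrackRecord(x, y, sample.luminance))
        state, cmds = step(state, sample, config, arena, rng)
        events += [c.payload for c in cmds if c.kind == "log_event"]
        last_t = sample.t
        if state.epoch == "ENDED":
            break
    truncated = state.epoch != "ENDED"
    if truncated:
        events.append(EventRecord("SESSION_TRUNCATED", round(last_t, 3),
                                  state.trial_index))
    return events, tracking, truncated
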