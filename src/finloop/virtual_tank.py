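"""Virtual tank: synthetic video generator and closed-loop test double.

Renders top-view frames of a simulated tank — a light uniform floor, one
elliptical fish blob of a distinct hue, and a screen-indicator strip whose
grey level encodes the task epoch — and drives a simple learning fish agent
so the full tracker -> task-engine -> screen loop runs with no hardware.

The agent is deliberately minimal: it perceives the task symbolically (it
reads the :class:`~finloop.engine.ScreenSpec`, not pixels — only the tracker
consumes pixels), learns cue values with the Rescorla-Wagner delta rule
``V <- V + alpha * (lambda - V)``, chooses between the two offered cues with
a softmax of inverse temperature beta, and swims toward its current goal
with a noisy heading.  It emulates goal-directed locomotion and incremental
reinforcement learning; it does not emulate fish vision, hydrodynamics, or
real response-time distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage import draw as _skdraw

from .arena import ArenaModel, CameraModel, cm_to_px
from .engine import (Command, ProtocolConfig, ScreenSpec, init_session,
                     render_screen, step)
from .io_logs import EventRecord, TrackRecord
from .tracking import TrackerConfig, TrackSample, track_frame

__all__ = [
    "FishAgent",
    "WorldState",
    "SessionResult",
    "compact_camera",
    "update_values",
    "choose_goal",
    "move_step",
    "render_frame",
    "simulate_session",
    "simulate_choice_sequence",
]

BACKGROUND_RGB = (235, 235, 235)
FISH_RGB = (230, 90, 40)  # orange body; hue sits near the red wrap point
OUTSIDE_CROP_GREY = 30


@dataclass(frozen=True)
class FishAgent:
    """Simulated subject: pose, locomotion parameters, and learned values.

    ``values`` maps cues to learned associative strengths in [0, 1]; the cue
    space is either the two sides or the stimulus colours, selected by
    ``cue_basis``.  ``alpha`` is the learning rate, ``beta`` the softmax
    inverse temperature (0 = indifferent chooser).
    """

    x: float = 15.0
    y: float = 40.0
    heading: float = 0.0  # radians in the tank frame
    speed_cm_s: float = 8.0
    body_length_cm: float = 8.0
    angular_noise_sd: float = 0.4  # rad / sqrt(s)
    turn_rate: float = 6.0  # 1/s relaxation toward the goal bearing
    alpha: float = 0.3
    beta: float = 5.0
    cue_basis: str = "side"  # "side" | "colour"
    values: dict[str, float] = field(
        default_factory=lambda: {"left": 0.5, "right": 0.5})

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not (7.0 <= self.body_length_cm <= 10.0):
            raise ValueError("body_length_cm outside the modelled 7-10 cm")
        if any(not 0 <= v <= 1 for v in self.values.values()):
            raise ValueError("values must lie in [0, 1]")


def naive_agent(cue_basis: str = "side", alpha: float = 0.3,
                beta: float = 5.0, **kw) -> FishAgent:
    if cue_basis == "side":
        values = {"left": 0.5, "right": 0.5}
    else:
        values = {c: 0.5 for c in ("red", "green", "blue", "white")}
    return FishAgent(cue_basis=cue_basis, alpha=alpha, beta=beta,
                     values=values, **kw)


@dataclass
class WorldState:
    agent: FishAgent
    screen: ScreenSpec
    pellets_pending: dict[str, int]
    t: float
    dt: float


def compact_camera(cm_per_px: float = 0.2, fps: float = 11.0) -> CameraModel:
    """A coarse, low-frame-rate camera for fast simulated sessions.

    Same geometry and pipeline as the full 1280x720 rig camera, at a scale
    that keeps multi-session simulations cheap.
    """
    crop_w = int(round(30.0 / cm_per_px))
    crop_h = int(round(60.0 / cm_per_px))
    return CameraModel(image_width_px=crop_w + 20, image_height_px=crop_h + 20,
                       fps=fps, crop_x=10, crop_y=10, crop_w=crop_w,
                       crop_h=crop_h, cm_per_px=cm_per_px)


def update_values(agent: FishAgent, chosen_cue: str,
                  rewarded: bool) -> FishAgent:
    """One Rescorla-Wagner update of the chosen cue's value."""
    if chosen_cue not in agent.values:
        raise KeyError(f"unknown cue {chosen_cue!r}")
    lam = 1.0 if rewarded else 0.0
    values = dict(agent.values)
    values[chosen_cue] += agent.alpha * (lam - values[chosen_cue])
    return replace(agent, values=values)


def _offered_cues(agent: FishAgent, screen: ScreenSpec) -> dict[str, str]:
    """Map side -> cue identity for the stimuli currently on screen."""
    if agent.cue_basis == "side":
        return {"left": "left", "right": "right"}
    cues = {}
    for stim in screen.stimuli:
        cues[stim.side] = stim.colour
    if set(cues) != {"left", "right"}:
        raise ValueError("colour-basis choice needs a stimulus on each side")
    return cues


def choose_goal(agent: FishAgent, screen: ScreenSpec,
                rng: np.random.Generator) -> str:
    """Softmax choice between the two offered sides.

    ``P(left) = exp(beta * V_left_cue) / (exp(beta * V_left_cue) +
    exp(beta * V_right_cue))``; with ``cue_basis="colour"`` the cue on each
    side is the circle colour shown there.
    """
    cues = _offered_cues(agent, screen)
    dv = agent.values[cues["left"]] - agent.values[cues["right"]]
    p_left = 1.0 / (1.0 + math.exp(-agent.beta * dv))
    return "left" if rng.random() < p_left else "right"


def _wrap_angle(a: float) -> float:
    return (a + math.pi) % (2 * math.pi) - math.pi


def move_step(agent: FishAgent, goal: tuple[float, float] | None, dt: float,
              arena: ArenaModel, rng: np.random.Generator) -> FishAgent:
    """Advance the agent one time step.

    The heading relaxes toward the goal bearing (or drifts as a random walk
    when no goal is set) with Gaussian angular noise; the position advances
    by ``speed * dt`` and reflects off the walls and the divider, so the
    agent never crosses the divider segment.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    heading = agent.heading
    if goal is not None:
        bearing = math.atan2(goal[1] - agent.y, goal[0] - agent.x)
        gain = min(1.0, agent.turn_rate * dt)
        heading = heading + gain * _wrap_angle(bearing - heading)
    noise = agent.angular_noise_sd * math.sqrt(dt)
    if noise > 0:
        heading += float(rng.normal(0.0, noise))
    heading = _wrap_angle(heading)

    x0, y0 = agent.x, agent.y
    x1 = x0 + agent.speed_cm_s * dt * math.cos(heading)
    y1 = y0 + agent.speed_cm_s * dt * math.sin(heading)

    tank = arena.tank
    margin = agent.body_length_cm / 2.0
    flip_x = flip_y = False
    lo_x, hi_x = margin, tank.width_cm - margin
    lo_y, hi_y = margin, tank.length_cm - margin
    if x1 < lo_x:
        x1, flip_x = 2 * lo_x - x1, True
    elif x1 > hi_x:
        x1, flip_x = 2 * hi_x - x1, True
    if y1 < lo_y:
        y1, flip_y = 2 * lo_y - y1, True
    elif y1 > hi_y:
        y1, flip_y = 2 * hi_y - y1, True

    # divider: vertical segment at mid-width from the screen wall inward
    div_x = arena.divider_x_cm
    div_len = tank.divider_length_cm
    if (x0 - div_x) * (x1 - div_x) < 0:
        # crossed the divider line; find the y where the path crosses it
        frac = (div_x - x0) / (x1 - x0)
        y_cross = y0 + frac * (y1 - y0)
        if y_cross <= div_len:
            x1, flip_x = 2 * div_x - x1, True
    if flip_x:
        heading = _wrap_angle(math.pi - heading)
    if flip_y:
        heading = _wrap_angle(-heading)
    x1 = min(max(x1, lo_x), hi_x)
    y1 = min(max(y1, lo_y), hi_y)
    return replace(agent, x=x1, y=y1, heading=heading)


def render_frame(world: WorldState, arena: ArenaModel,
                 draw_agent: bool = True) -> np.ndarray:
    """Render one top-view RGB camera frame of the virtual tank.

    Uniform light floor inside the crop, dark surround outside, the fish as a
    filled rotated ellipse (width 0.35 of the body length), and the
    screen-indicator strip along the screen edge at the current epoch level.
    Deterministic given the world state.
    """
    cam = arena.camera
    frame = np.full((cam.image_height_px, cam.image_width_px, 3),
                    OUTSIDE_CROP_GREY, dtype=np.uint8)
    frame[cam.crop_y:cam.crop_y + cam.crop_h,
          cam.crop_x:cam.crop_x + cam.crop_w] = BACKGROUND_RGB

    if draw_agent:
        ag = world.agent
        col, row = cm_to_px((ag.x, ag.y), cam, arena.tank)
        half_len = ag.body_length_cm / 2.0 / cam.cm_per_px
        half_wid = 0.35 * ag.body_length_cm / 2.0 / cam.cm_per_px
        # tank heading angle maps directly to the (col, row) pixel frame
        rr, cc = _skdraw.ellipse(row, col, half_wid, half_len,
                                 rotation=-ag.heading,
                                 shape=frame.shape[:2])
        frame[rr, cc] = FISH_RGB

    # indicator strip: first 1 cm of the tank image at the screen edge,
    # drawn last (it images the screen, which nothing in the tank occludes)
    strip_rows = max(1, int(round(1.0 / cam.cm_per_px)))
    level = world.screen.epoch_indicator_level
    frame[cam.crop_y:cam.crop_y + strip_rows,
          cam.crop_x:cam.crop_x + cam.crop_w] = level
    return frame


def _zone_goal(arena: ArenaModel, side: str) -> tuple[float, float]:
    return arena.rois[f"choice_{side}"].rect.centre


def _navigate(agent: FishAgent, target: tuple[float, float],
              arena: ArenaModel) -> tuple[float, float]:
    """Waypoint routing around the divider.

    If the straight path to the target would cross the divider segment, head
    for a point just beyond the divider's end on the target's side first.
    """
    div_x = arena.divider_x_cm
    div_len = arena.tank.divider_length_cm
    same_side = (agent.x - div_x) * (target[0] - div_x) > 0
    if same_side or (agent.y > div_len and target[1] > div_len):
        return target
    if target[1] <= div_len <= agent.y:
        # swing wide of the divider tip before diving into the arm
        off = 5.0 if target[0] > div_x else -5.0
        if abs(agent.x - (div_x + off)) > 3.0 or agent.y > div_len + 8.0:
            return (div_x + off, div_len + 5.0)
        return target
    if agent.y <= div_len <= target[1]:
        # leave the arm toward the open back of the tank first
        return (agent.x, div_len + 8.0)
    return target


@dataclass
class SessionResult:
    """Everything one simulated session produces.

    ``poses`` holds the agent's true (x, y) tank position at each frame, so
    tracking accuracy can be audited against ground truth; ``pellets`` the
    per-side dispense counts; ``value_trajectory`` one record per completed
    trial with the post-update cue values.
    """

    events: list[EventRecord]
    tracking: list[TrackRecord]
    trials: pd.DataFrame
    value_trajectory: list[dict]
    agent: FishAgent
    poses: list[tuple[float, float]]
    pellets: dict[str, int]


def simulate_session(config: ProtocolConfig, arena: ArenaModel,
                     agent: FishAgent, seed: int,
                     tracker: TrackerConfig | None = None,
                     max_frames: int | None = None) -> SessionResult:
    """Run one complete closed-loop session in the virtual tank.

    Per frame: render -> track -> state-machine step -> apply screen and
    dispense commands; the agent updates its cue values on each outcome and
    re-plans its goal (start zone while a trial is available, the
    softmax-chosen choice zone while stimuli are on, an undirected walk
    otherwise).  Fully reproducible from ``seed``.
    """
    from .analysis import events_to_trials  # deferred: avoids module cycle

    rng = np.random.default_rng(seed)
    tracker = tracker or TrackerConfig()
    dt = 1.0 / arena.camera.fps
    state, cmds = init_session(config, arena, rng)
    screen = next(c.payload for c in cmds if c.kind == "set_screen")
    world = WorldState(agent=agent, screen=screen,
                       pellets_pending={"left": 0, "right": 0}, t=0.0, dt=dt)
    events: list[EventRecord] = [c.payload for c in cmds
                                 if c.kind == "log_event"]
    tracking: list[TrackRecord] = []
    poses: list[tuple[float, float]] = []
    value_traj: list[dict] = []
    side_cues: dict[str, str] = {}
    chosen_goal: str | None = None
    registered_side: str | None = None  # side latched by the controller

    if max_frames is None:
        max_frames = int(config.session_timeout_s / dt) + 2

    for frame_index in range(1, max_frames + 1):
        t = frame_index * dt
        frame = render_frame(world, arena)
        poses.append((world.agent.x, world.agent.y))
        sample = track_frame(frame, arena, tracker, frame_index, t)
        x, y = (sample.centroid if sample.centroid is not None
                else (None, None))
        tracking.append(TrackRecord(x, y, sample.luminance))

        prev_epoch = state.epoch
        state, cmds = step(state, sample, config, arena, rng)
        for c in cmds:
            if c.kind == "set_screen":
                world.screen = c.payload
            elif c.kind == "dispense_pellet":
                world.pellets_pending[c.payload] += 1
            elif c.kind == "log_event":
                events.append(c.payload)
        # agent learning: act on choice/outcome events emitted this frame
        for c in cmds:
            if c.kind != "log_event":
                continue
            ev = c.payload
            if ev.name == "CHOICE_LEFT":
                registered_side = "left"
            elif ev.name == "CHOICE_RIGHT":
                registered_side = "right"
            elif ev.name in ("REWARD", "OMISSION") and registered_side:
                cue = side_cues.get(registered_side, registered_side)
                world.agent = update_values(world.agent, cue,
                                            ev.name == "REWARD")
                value_traj.append({"trial": ev.code,
                                   "rewarded": ev.name == "REWARD",
                                   "chosen_side": registered_side,
                                   **dict(world.agent.values)})
                registered_side = None
                chosen_goal = None

        if state.epoch == "ENDED":
            break

        # re-plan
        if state.epoch == "STIMULUS_ON":
            if prev_epoch != "STIMULUS_ON" or chosen_goal is None:
                side_cues = _offered_cues(world.agent, world.screen) \
                    if world.screen.stimuli else {"left": "left",
                                                  "right": "right"}
                if len(world.screen.stimuli) == 1:
                    # pre-training: head for the signalled side
                    chosen_goal = world.screen.stimuli[0].side
                else:
                    chosen_goal = choose_goal(world.agent, world.screen, rng)
            goal = _navigate(world.agent, _zone_goal(arena, chosen_goal),
                             arena)
        elif state.epoch == "TRIAL_AVAILABLE":
            goal = _navigate(world.agent, arena.rois["start"].rect.centre,
                             arena)
        else:  # ITI / OUTCOME_DELAY: undirected
            goal = None
        world.agent = move_step(world.agent, goal, dt, arena, rng)
        world.t = t

    if state.epoch != "ENDED":
        events.append(EventRecord("SESSION_TRUNCATED",
                                  round(world.t, 3), state.trial_index))
    trials = events_to_trials(events)
    return SessionResult(events=events, tracking=tracking, trials=trials,
                         value_trajectory=value_traj, agent=world.agent,
                         poses=poses, pellets=dict(world.pellets_pending))


def simulate_choice_sequence(config: ProtocolConfig, agent: FishAgent,
                             seed: int) -> tuple[pd.DataFrame, FishAgent]:
    """Trial-level simulation of the value-learning loop, no locomotion.

    Runs the same contingency assignment, softmax choice and Rescorla-Wagner
    update as the full virtual tank, but skips rendering, tracking and
    movement entirely — one iteration per trial.  Useful for asymptotic
    properties of the learning rule (hundreds of trials) where the video
    loop adds nothing but cost.
    """
    from .engine import assign_trial_contingency  # local import for clarity

    rng = np.random.default_rng(seed)
    a = config.contingency
    rows = []
    for trial in range(config.n_trials):
        s_plus_side = assign_trial_contingency(config, trial, rng)
        if agent.cue_basis == "colour":
            cues = {s_plus_side: a.s_plus_colour,
                    ("right" if s_plus_side == "left" else "left"):
                        a.s_minus_colour}
        else:
            cues = {"left": "left", "right": "right"}
        dv = agent.values[cues["left"]] - agent.values[cues["right"]]
        p_left = 1.0 / (1.0 + math.exp(-agent.beta * dv))
        chosen = "left" if rng.random() < p_left else "right"
        correct = chosen == s_plus_side
        agent = update_values(agent, cues[chosen], correct)
        rows.append({"trial": trial, "chosen_side": chosen,
                     "s_plus_side": s_plus_side, "correct": correct,
                     "rewarded": correct, **dict(agent.values)})
    return pd.DataFrame(rows), agent
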