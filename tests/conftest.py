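"""Shared fixtures: arenas, fast protocol configs, and cached simulations.

Closed-loop simulations are expensive (every frame is rendered and tracked),
so the ones several tests share are session-scoped.  Fast variants use the
coarse ``compact_camera`` and shortened ITIs / outcome delays; neither enters
any asserted quantity (choice proportions, reward counts, centroid errors).
"""

from __future__ import annotations

import numpy as np
import pytest

from finloop import (FishAgent, default_arena, naive_agent, compact_camera,
                     simulate_session)
from finloop.engine import ColourAssignment, protocol_preset
from finloop.io_logs import SupplementPanels
from finloop.virtual_tank import simulate_choice_sequence


@pytest.fixture(scope="session")
def arena_full():
    return default_arena()


@pytest.fixture(scope="session")
def arena_fast():
    return default_arena(camera=compact_camera())


def fast_config(phase: str, **overrides):
    """Phase preset with short timing for simulated sessions."""
    kw = dict(iti_min_s=1.0, iti_max_s=2.0, outcome_delay_s=1.0,
              session_timeout_s=1e6)
    kw.update(overrides)
    return protocol_preset(phase, **kw)


@pytest.fixture(scope="session")
def greedy_session(arena_fast):
    """A fully pre-trained (greedy) agent on a 24-trial acquisition session."""
    config = fast_config("acquisition", rng_seed=11)
    agent = FishAgent(values={"left": 1.0, "right": 0.0}, beta=20.0)
    return simulate_session(config, arena_fast, agent, seed=11)


@pytest.fixture(scope="session")
def beta0_session(arena_fast):
    """An indifferent (beta = 0) chooser over 200 trial-randomised trials."""
    config = fast_config("colour_random", rng_seed=7, n_trials=200)
    agent = naive_agent(cue_basis="colour", beta=0.0)
    return simulate_session(config, arena_fast, agent, seed=7)


@pytest.fixture(scope="session")
def acq_rev_run(arena_fast):
    """Side-learning agent through acquisition then reversal sessions.

    Two 24-trial acquisition sessions followed by three reversal sessions,
    carrying the agent's learned values across sessions; returns the list of
    (phase, SessionResult) in order.
    """
    agent = naive_agent(cue_basis="side", alpha=0.3, beta=5.0)
    contingency = ColourAssignment(s_plus_side="left")
    out = []
    seed = 100
    for phase, n_sessions in (("acquisition", 2), ("reversal", 3)):
        for k in range(n_sessions):
            config = fast_config(phase, contingency=contingency,
                                 rng_seed=seed + k)
            res = simulate_session(config, arena_fast, agent, seed=seed + k)
            agent = res.agent
            out.append((phase, res))
        seed += 10
    return out


def make_synthetic_supplement(seed: int = 0) -> SupplementPanels:
    """Synthetic stand-in for the five-panel per-subject workbook.

    Built from the trial-level learning simulator for five simulated
    subjects, with log-normal movement-time panels; it has the documented
    layout and realistic learning curves but is NOT the published data —
    tests using it check the pipeline's arithmetic, not the printed group
    statistics.
    """
    rng = np.random.default_rng(seed)
    n_subj = 5
    panelA = np.zeros((12, n_subj))
    panelB = np.zeros((25, n_subj))
    panelE = np.zeros((48, n_subj), dtype=int)
    for s in range(n_subj):
        agent = naive_agent(cue_basis="side", alpha=0.25, beta=4.0)
        for sess in range(5):
            cfg = protocol_preset("acquisition", rng_seed=seed)
            df, agent = simulate_choice_sequence(
                cfg, agent, seed=int(rng.integers(2**31)))
            panelA[sess, s] = df["correct"].mean()
        for sess in range(7):
            cfg = protocol_preset("reversal", rng_seed=seed)
            df, agent = simulate_choice_sequence(
                cfg, agent, seed=int(rng.integers(2**31)))
            panelA[5 + sess, s] = df["correct"].mean()
        agent = naive_agent(cue_basis="colour", alpha=0.15, beta=3.0)
        for sess in range(25):
            cfg = protocol_preset("colour_random", rng_seed=seed)
            df, agent = simulate_choice_sequence(
                cfg, agent, seed=int(rng.integers(2**31)))
            panelB[sess, s] = df["correct"].mean()
            if sess == 0:
                panelE[:24, s] = df["correct"].astype(int)
            elif sess == 24:
                panelE[24:, s] = df["correct"].astype(int)
    panelC = rng.lognormal(mean=2.0, sigma=0.4, size=(n_subj, 6))
    panelD = rng.lognormal(mean=1.0, sigma=0.3, size=(n_subj, 4))
    return SupplementPanels(panelA=panelA, panelB=panelB, panelC=panelC,
                            panelD=panelD, panelE=panelE.astype(float))


@pytest.fixture(scope="session")
def synthetic_supplement():
    return make_synthetic_supplement(seed=3)
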