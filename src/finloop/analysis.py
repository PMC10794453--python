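"""Behavioural metrics and statistics from session logs.

Reconstructs per-trial records (initiation time, response time, choice,
correctness, reward) from the timestamped event list, summarises sessions
(choice proportions, median movement times, tercile splits), and runs the
statistical battery used for group-level inference on this task: the arcsine
square-root transform for proportions, one-sided one-sample t tests against
chance, paired t tests, and one-way repeated-measures ANOVA with subject as
the blocking factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .arena import ArenaModel
from .io_logs import EventRecord, SupplementPanels, TrackRecord

__all__ = [
    "StatResult",
    "events_to_trials",
    "proportion_correct",
    "arcsine_sqrt",
    "t_one_sample",
    "t_paired",
    "rm_anova_oneway",
    "tercile_split",
    "session_summary",
    "occupancy_histogram",
    "reproduce_fig3",
]

CHANCE = 0.5


@dataclass(frozen=True)
class StatResult:
    statistic: float
    df: tuple[float, ...]
    p_value: float
    tails: str  # "one" | "two"
    transform_applied: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


# ---------------------------------------------------------------------------
# trial reconstruction

TRIAL_COLUMNS = ["trial", "iti_s", "initiation_time_s", "response_time_s",
                 "chosen_side", "s_plus_side", "correct", "rewarded"]


def events_to_trials(events: list[EventRecord]) -> pd.DataFrame:
    """Reconstruct the per-trial table from a session event list.

    One row per *completed* trial (a trial with an outcome event); a trial
    cut short by session end is excluded.  Initiation time is
    TRIAL_AVAILABLE -> START_ENTRY, response time is STIM_ON -> choice.
    Sessions without a start gate (choice-zone pre-training) yield NaN
    initiation times.

    Raises ``ValueError`` for orphan events (a choice with no preceding
    stimulus onset).
    """
    rows = []
    cur: dict = {}
    iti_t = None
    for ev in events:
        if ev.name == "ITI_START":
            iti_t = ev.t
            cur = {}
        elif ev.name == "TRIAL_AVAILABLE":
            cur["available_t"] = ev.t
            if iti_t is not None:
                cur["iti_s"] = ev.t - iti_t
        elif ev.name == "START_ENTRY":
            cur["start_t"] = ev.t
        elif ev.name == "STIM_ON":
            cur["stim_t"] = ev.t
            if iti_t is not None and "iti_s" not in cur:
                cur["iti_s"] = ev.t - iti_t  # no start gate in this protocol
        elif ev.name in ("CHOICE_LEFT", "CHOICE_RIGHT"):
            if "stim_t" not in cur:
                raise ValueError(
                    f"orphan choice event at t={ev.t} (no STIM_ON)")
            cur["choice_t"] = ev.t
            cur["chosen_side"] = ("left" if ev.name == "CHOICE_LEFT"
                                  else "right")
            cur["correct"] = bool(ev.code)
        elif ev.name in ("REWARD", "OMISSION"):
            if "choice_t" not in cur:
                raise ValueError(
                    f"orphan outcome event at t={ev.t} (trial {ev.code})")
            chosen = cur["chosen_side"]
            correct = cur["correct"]
            s_plus = chosen if correct else ("right" if chosen == "left"
                                             else "left")
            init_t = (cur["start_t"] - cur["available_t"]
                      if "start_t" in cur and "available_t" in cur
                      else math.nan)
            rows.append({
                "trial": ev.code,
                "iti_s": cur.get("iti_s", math.nan),
                "initiation_time_s": init_t,
                "response_time_s": cur["choice_t"] - cur["stim_t"],
                "chosen_side": chosen,
                "s_plus_side": s_plus,
                "correct": correct,
                "rewarded": ev.name == "REWARD",
            })
            cur = {}
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    if len(df) and (df["rewarded"] & ~df["correct"]).any():
        raise ValueError("log inconsistency: reward on an incorrect trial")
    return df


def proportion_correct(trials: pd.DataFrame) -> float:
    if len(trials) == 0:
        raise ValueError("empty trial table")
    return float(trials["correct"].mean())


def tercile_split(items) -> list:
    """Split a sequence in session order into contiguous terciles.

    The first/middle/last thirds partition the input; when the length is not
    divisible by three, the remainder goes to the earliest bins (25 items ->
    9, 8, 8).
    """
    items = list(items)
    n = len(items)
    if n < 3:
        raise ValueError("need at least 3 items for a tercile split")
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    bins, idx = [], 0
    for s in sizes:
        bins.append(items[idx:idx + s])
        idx += s
    return bins


def session_summary(trials: pd.DataFrame) -> dict:
    """Per-session summary: proportion correct, median times, terciles."""
    if len(trials) == 0:
        raise ValueError("empty trial table")
    correct = trials[trials["correct"]]
    incorrect = trials[~trials["correct"]]
    terciles = tercile_split(trials["correct"].tolist())
    return {
        "n_trials": int(len(trials)),
        "proportion_correct": proportion_correct(trials),
        "median_initiation_s": float(trials["initiation_time_s"].median()),
        "median_response_s": float(trials["response_time_s"].median()),
        "median_response_correct_s": float(
            correct["response_time_s"].median()) if len(correct) else math.nan,
        "median_response_incorrect_s": float(
            incorrect["response_time_s"].median()) if len(incorrect)
            else math.nan,
        "tercile_proportions": [float(np.mean(b)) for b in terciles],
    }


# ---------------------------------------------------------------------------
# statistics

def arcsine_sqrt(p):
    """Variance-stabilising transform for proportions: asin(sqrt(p))."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def t_one_sample(values, mu0: float, tails: str = "one_greater",
                 transform_applied: bool = False) -> StatResult:
    """One-sample t test of the mean against ``mu0``.

    Default alternative is "greater" (one-sided), matching a
    performance-above-chance test.  Raises for fewer than two values or zero
    variance.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    if np.ptp(values) == 0:
        raise ValueError("degenerate input: zero variance")
    alternative = {"one_greater": "greater", "one_less": "less",
                   "two": "two-sided"}[tails]
    res = stats.ttest_1samp(values, popmean=mu0, alternative=alternative)
    return StatResult(float(res.statistic), (float(values.size - 1),),
                      float(res.pvalue),
                      "two" if tails == "two" else "one", transform_applied)


def t_paired(x, y, tails: str = "two",
             transform_applied: bool = False) -> StatResult:
    """Paired t test (a one-sample t on the differences)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    if np.ptp(x - y) == 0:
        raise ValueError("degenerate input: zero-variance differences")
    alternative = {"one_greater": "greater", "one_less": "less",
                   "two": "two-sided"}[tails]
    res = stats.ttest_rel(x, y, alternative=alternative)
    return StatResult(float(res.statistic), (float(x.size - 1),),
                      float(res.pvalue),
                      "two" if tails == "two" else "one", transform_applied)


def rm_anova_oneway(matrix, transform_applied: bool = False) -> StatResult:
    """One-way repeated-measures ANOVA on a subjects x conditions matrix.

    The total sum of squares is partitioned into condition, subject, and
    error terms; ``F = MS_cond / MS_error`` with df ``(k - 1, (k - 1)(n - 1))``
    for n subjects and k conditions.  Missing cells raise (no imputation).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("matrix must be 2-D (subjects x conditions)")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    if np.isnan(m).any():
        raise ValueError("missing cells are not supported")
    grand = m.mean()
    ss_cond = n * ((m.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((m.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((m - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    if ms_err == 0:
        if ms_cond == 0:  # e.g. identical columns: no condition effect
            return StatResult(0.0, (float(df_cond), float(df_err)), 1.0,
                              "one", transform_applied)
        raise ValueError("degenerate input: zero error variance")
    f = ms_cond / ms_err
    p = float(stats.f.sf(f, df_cond, df_err))
    return StatResult(float(f), (float(df_cond), float(df_err)), p,
                      "one", transform_applied)


def oneway_anova(matrix) -> StatResult:
    """Plain (non-repeated) one-way ANOVA treating columns as groups.

    Used to probe the alternative reading of tercile analyses whose printed
    degrees of freedom do not match a repeated-measures layout.
    """
    m = np.asarray(matrix, dtype=float)
    res = stats.f_oneway(*[m[:, j] for j in range(m.shape[1])])
    k = m.shape[1]
    df1, df2 = k - 1, m.size - k
    return StatResult(float(res.statistic), (float(df1), float(df2)),
                      float(res.pvalue), "one")


# ---------------------------------------------------------------------------
# occupancy

def occupancy_histogram(tracking: list[TrackRecord], arena: ArenaModel,
                        bins: int | tuple[int, int] = 30) -> np.ndarray:
    """2-D histogram of frame counts over the cropped tank image.

    Frames without a centroid are skipped; the grid sums to the number of
    frames with a valid centroid.  Returned with shape (rows_bins, col_bins)
    matching the image orientation.
    """
    if not tracking:
        raise ValueError("empty tracking log")
    cam = arena.camera
    xs = np.array([r.x for r in tracking if r.x is not None], dtype=float)
    ys = np.array([r.y for r in tracking if r.y is not None], dtype=float)
    if isinstance(bins, int):
        bins = (bins, bins)
    grid, _, _ = np.histogram2d(
        ys, xs, bins=bins, range=[[0, cam.crop_h], [0, cam.crop_w]])
    return grid


# ---------------------------------------------------------------------------
# published-figure statistics

def reproduce_fig3(supp: SupplementPanels) -> dict:
    """Recompute the group statistics behind the published results figure.

    From the five-panel per-subject data: session repeated-measures ANOVAs
    (on arcsine-sqrt-transformed proportions, with the untransformed value
    alongside for comparison), terminal-session means and one-sided t tests
    against chance, the paired response-time test, and the tercile
    choice/initiation analyses under both a repeated-measures and a plain
    one-way layout (the published tercile degrees of freedom are ambiguous
    between the two).
    """
    out: dict = {}
    mu0_t = arcsine_sqrt(CHANCE)

    acq = supp.panelA[:5]     # sessions x subjects
    rev = supp.panelA[5:]
    exp2 = supp.panelB

    def session_block(name, block):
        subj_by_sess = block.T  # subjects x sessions
        out[f"{name}_rm_anova"] = rm_anova_oneway(
            arcsine_sqrt(subj_by_sess), transform_applied=True)
        out[f"{name}_rm_anova_untransformed"] = rm_anova_oneway(subj_by_sess)
        final = block[-1]
        out[f"{name}_final_mean"] = float(final.mean())
        out[f"{name}_final_sem"] = float(final.std(ddof=1)
                                         / math.sqrt(final.size))
        out[f"{name}_final_t_vs_chance"] = t_one_sample(
            arcsine_sqrt(final), mu0_t, transform_applied=True)

    session_block("acquisition", acq)
    session_block("reversal", rev)
    session_block("exp2", exp2)

    # response times toward S+ vs S-, first and last sessions
    out["response_time_first_paired_t"] = t_paired(
        supp.panelD[:, 0], supp.panelD[:, 2])
    out["response_time_last_paired_t"] = t_paired(
        supp.panelD[:, 1], supp.panelD[:, 3])

    # initiation times: first vs last session (subject means over terciles)
    out["initiation_first_vs_last_paired_t"] = t_paired(
        supp.panelC[:, :3].mean(axis=1), supp.panelC[:, 3:].mean(axis=1))

    # within-session tercile trends in choices, first and last sessions
    for label, rows in (("first", supp.panelE[:24]),
                        ("last", supp.panelE[24:])):
        terc = np.stack([np.mean(b, axis=0)
                         for b in tercile_split(list(rows))], axis=1)
        # terc: subjects x 3 tercile proportions
        out[f"choice_terciles_{label}_rm_anova"] = rm_anova_oneway(
            arcsine_sqrt(terc), transform_applied=True)
        out[f"choice_terciles_{label}_oneway_anova"] = oneway_anova(
            arcsine_sqrt(terc))
    return out


def format_report(results: dict) -> str:
    """Plain-text rendering of a statistics dictionary."""
    lines = []
    for key, val in results.items():
        if isinstance(val, StatResult):
            df = ",".join(f"{d:g}" for d in val.df)
            stat = "F" if len(val.df) == 2 else "t"
            note = " (arcsine-sqrt)" if val.transform_applied else ""
            lines.append(f"{key}: {stat}({df}) = {val.statistic:.3f}, "
                         f"p = {val.p_value:.4g} [{val.tails}-tailed]{note}")
        else:
            lines.append(f"{key}: {val:.4f}" if isinstance(val, float)
                         else f"{key}: {val}")
    return "\n".join(lines)
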