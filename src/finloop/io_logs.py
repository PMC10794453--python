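"""Readers and writers for the platform's session files.

Two comma-separated files are produced per session, both headerless:

* the **event list** — one row per task event, ``name,t,code`` with the
  timestamp in session-relative seconds at 3 decimal places and an integer
  code carrying per-event disambiguation (the trial index for most events;
  for choice events, 1 if the chosen side carried S+ and 0 otherwise);
* the **tracking file** — one row per processed frame, ``x,y,luminance``;
  the centroid fields are left empty on frames where no blob was found.

A reader for the five-panel supplementary workbook layout (per-subject
session proportions, tercile initiation-time medians, response-time medians
and raw choice vectors) is also provided, accepting either a spreadsheet
workbook or a directory of per-tab CSV exports with identical layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EventRecord",
    "TrackRecord",
    "SupplementPanels",
    "EVENT_NAMES",
    "write_events",
    "read_events",
    "write_tracking",
    "read_tracking",
    "read_supplement",
]

# Fixed event vocabulary; the code column is the trial index except for
# CHOICE_* where it flags whether the chosen side carried S+.
EVENT_NAMES = (
    "ITI_START", "TRIAL_AVAILABLE", "START_ENTRY", "STIM_ON",
    "CHOICE_LEFT", "CHOICE_RIGHT", "REWARD", "OMISSION", "SESSION_END",
    "SESSION_TRUNCATED",
)


@dataclass(frozen=True)
class EventRecord:
    name: str
    t: float
    code: int

    def __post_init__(self) -> None:
        if self.name not in EVENT_NAMES:
            raise ValueError(f"unknown event name {self.name!r}")


@dataclass(frozen=True)
class TrackRecord:
    x: float | None
    y: float | None
    luminance: float


def write_events(records: list[EventRecord], path) -> None:
    """Write the event list; deterministic, byte-identical for equal input."""
    with open(path, "w", newline="") as fh:
        for r in records:
            fh.write(f"{r.name},{r.t:.3f},{r.code}\n")


def read_events(path, strict: bool = True) -> list[EventRecord]:
    """Parse an event list.

    Raises ``ValueError`` naming the offending line for malformed rows.  With
    ``strict`` a non-monotonic timestamp raises; otherwise it is tolerated
    (the analysis layer re-validates).
    """
    records: list[EventRecord] = []
    prev_t = -math.inf
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 fields, "
                                 f"got {len(parts)}")
            name, t_str, code_str = parts
            try:
                t = float(t_str)
                code = int(code_str)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            if name not in EVENT_NAMES:
                raise ValueError(f"{path}: line {lineno}: unknown event "
                                 f"name {name!r}")
            if t < prev_t and strict:
                raise ValueError(f"{path}: line {lineno}: non-monotonic "
                                 f"timestamp {t} after {prev_t}")
            prev_t = t
            records.append(EventRecord(name, round(t, 3), code))
    return records


def write_tracking(records: list[TrackRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        for r in records:
            x = "" if r.x is None else f"{r.x:.3f}"
            y = "" if r.y is None else f"{r.y:.3f}"
            fh.write(f"{x},{y},{r.luminance:.3f}\n")


def read_tracking(path) -> list[TrackRecord]:
    records: list[TrackRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 fields, "
                                 f"got {len(parts)}")
            x_str, y_str, lum_str = parts
            try:
                x = float(x_str) if x_str else None
                y = float(y_str) if y_str else None
                lum = float(lum_str)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            if (x is None) != (y is None):
                raise ValueError(f"{path}: line {lineno}: centroid fields "
                                 "must both be present or both empty")
            records.append(TrackRecord(x, y, lum))
    return records


# ---------------------------------------------------------------------------
# supplementary workbook

_PANELS = ("panelA", "panelB", "panelC", "panelD", "panelE")
_N_SUBJECTS = 5


@dataclass(frozen=True)
class SupplementPanels:
    """The five-panel per-subject data behind the group statistics.

    ``panelA``: proportion correct, 12 sessions (5 acquisition + 7 reversal)
    x 5 subjects.  ``panelB``: proportion correct for the trial-randomised
    colour discrimination, 25 sessions x 5 subjects.  ``panelC``: per-subject
    median initiation times for the first session's terciles (3 columns) then
    the last session's terciles (3 columns).  ``panelD``: per-subject median
    response times toward S+ on the first and last sessions (2 columns) then
    toward S- (2 columns).  ``panelE``: per-subject choice vectors for the
    first and last colour-discrimination sessions concatenated (24 + 24
    rows), 1 marking an S+ choice.
    """

    panelA: np.ndarray
    panelB: np.ndarray
    panelC: np.ndarray
    panelD: np.ndarray
    panelE: np.ndarray

    def __post_init__(self) -> None:
        checks = {
            "panelA": (self.panelA, (12, _N_SUBJECTS)),
            "panelB": (self.panelB, (25, _N_SUBJECTS)),
            "panelC": (self.panelC, (_N_SUBJECTS, 6)),
            "panelD": (self.panelD, (_N_SUBJECTS, 4)),
            "panelE": (self.panelE, (48, _N_SUBJECTS)),
        }
        for name, (arr, shape) in checks.items():
            if arr.shape != shape:
                raise ValueError(f"{name}: expected shape {shape}, "
                                 f"got {arr.shape}")
        for name in ("panelA", "panelB"):
            arr = checks[name][0]
            if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
                raise ValueError(f"{name}: proportions must lie in [0, 1]")
        if not np.isin(self.panelE, (0, 1)).all():
            raise ValueError("panelE: entries must be 0 or 1")


def _read_panel_csv(path: Path) -> np.ndarray:
    return pd.read_csv(path, header=None).to_numpy(dtype=float)


def read_supplement(path) -> SupplementPanels:
    """Read the supplementary panels from a workbook or a CSV directory.

    ``path`` may be an ``.xlsx`` workbook with tabs panelA..panelE, or a
    directory containing ``panelA.csv`` .. ``panelE.csv`` with the same
    layout (headerless numeric matrices).  Raises ``ValueError`` naming the
    missing tab or the tab whose shape does not match the documented layout.
    """
    path = Path(path)
    panels: dict[str, np.ndarray] = {}
    if path.is_dir():
        for name in _PANELS:
            f = path / f"{name}.csv"
            if not f.exists():
                raise ValueError(f"missing panel file {f.name} in {path}")
            panels[name] = _read_panel_csv(f)
    else:
        if not path.exists():
            raise FileNotFoundError(path)
        sheets = pd.read_excel(path, sheet_name=None, header=None)
        for name in _PANELS:
            if name not in sheets:
                raise ValueError(f"workbook {path.name} is missing tab {name!r}")
            panels[name] = sheets[name].to_numpy(dtype=float)
    try:
        return SupplementPanels(**panels)
    except ValueError as exc:
        raise ValueError(f"supplement layout error: {exc}") from None
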