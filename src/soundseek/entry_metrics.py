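"""Chamber-entry detection, entry taxonomy, and center-path metrics.

A chamber entry is the first video frame on which the snout passes into a
chamber; an occupancy run ends when the snout returns to the center (or
leaves the arena).  Entries are classified as:

* duplicate - the chamber was already entered on the same trial;
* previous-reward return - the chamber holds the previously rewarded port;
* cycling - the chamber is ring-adjacent to the one just exited;
* with poke vs. check - whether a poke into that chamber's port occurred
  during the occupancy interval (a check is an entry without poke,
  interpreted as sampling the chamber for sound).

Center-path segments are scored by mean speed and straightness
(D_straight / D_actual: endpoint distance over path length, 1 for a
straight crossing, -> 0 for a looping path).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import arena
from .arena import CENTER, OUTSIDE, ArenaGeometry, is_adjacent
from .pose import PoseTrack
from .task import TrialRecord

DEBOUNCE_FRAMES = 2      # 67 ms at 30 fps; suppresses boundary chatter
MIN_CENTER_FRAMES = 3
MAX_INTERP_GAP = 5       # missing-snout gaps longer than this split runs
STILL_THRESHOLD_CM_S = 0.5


@dataclass
class ChamberEntry:
    chamber: int
    entry_frame: int
    exit_frame: int          # exclusive
    trial_idx: int | None = None
    duplicate: bool = False
    prev_reward_return: bool = False
    cycling: bool = False
    with_poke: bool = False


@dataclass(frozen=True)
class PathSegment:
    start_frame: int
    end_frame: int           # exclusive
    d_straight: float        # cm
    d_actual: float          # cm
    straightness: float
    mean_speed: float        # cm/s
    region: str = "center"


# -- helpers -----------------------------------------------------------------

def _snout_cm(pose: PoseTrack, geom: ArenaGeometry, part: str = "snout") -> np.ndarray:
    xy = pose.part(part)
    if pose.units == "px":
        xy = arena.cm_from_px(geom, xy)
    return xy


def _interp_gaps(xy: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly interpolate NaN runs of length <= max_gap (per coordinate)."""
    out = xy.copy()
    valid = np.isfinite(xy).all(axis=1)
    if valid.all() or not valid.any():
        return out
    idx = np.arange(len(xy))
    # identify NaN runs
    missing = ~valid
    starts = np.flatnonzero(missing & ~np.r_[False, missing[:-1]])
    ends = np.flatnonzero(missing & ~np.r_[missing[1:], False]) + 1
    for s, e in zip(starts, ends):
        if e - s <= max_gap and s > 0 and e < len(xy):
            for c in (0, 1):
                out[s:e, c] = np.interp(idx[s:e], [s - 1, e], [xy[s - 1, c], xy[e, c]])
    return out


def _label_runs(labels: np.ndarray):
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.r_[0, change]
    ends = np.r_[change, len(labels)]
    return [(int(labels[s]), int(s), int(e)) for s, e in zip(starts, ends)]


def _debounced_labels(labels: np.ndarray, debounce: int) -> np.ndarray:
    """Merge sub-debounce center/outside blips flanked by the same chamber.

    Positional jitter near an entry line produces single-frame label
    flicker; a short non-chamber run sandwiched between two runs of the
    same chamber is boundary chatter, not a real exit.
    """
    labels = labels.copy()
    runs = _label_runs(labels)
    for i in range(1, len(runs) - 1):
        lab, s, e = runs[i]
        if lab >= 0 or e - s >= debounce:
            continue
        prev_lab = runs[i - 1][0]
        next_lab = runs[i + 1][0]
        if prev_lab == next_lab and prev_lab >= 0:
            labels[s:e] = prev_lab
    return labels


# -- operations --------------------------------------------------------------

def detect_entries(pose: PoseTrack, geom: ArenaGeometry,
                   debounce_frames: int = DEBOUNCE_FRAMES,
                   max_gap: int = MAX_INTERP_GAP,
                   part: str = "snout") -> list[ChamberEntry]:
    """Ordered chamber entries from a snout trajectory.

    One entry per maximal chamber-occupancy run of at least
    ``debounce_frames`` frames; center/outside frames (and untracked gaps
    longer than ``max_gap``) separate runs.
    """
    xy = _snout_cm(pose, geom, part)
    if not np.isfinite(xy).any():
        raise ValueError(f"no {part} data in pose track")
    xy = _interp_gaps(xy, max_gap)
    labels = arena.classify_points(geom, xy)
    labels = _debounced_labels(labels, debounce_frames)
    entries = []
    for lab, s, e in _label_runs(labels):
        if lab >= 0 and e - s >= debounce_frames:
            entries.append(ChamberEntry(chamber=lab, entry_frame=s, exit_frame=e))
    return entries


def entries_from_trial(trial: TrialRecord, fps: float = 30.0) -> list[ChamberEntry]:
    """Ground-truth ChamberEntries from a simulated trial's event log."""
    out = []
    for i, ev in enumerate(trial.entries):
        f0 = int(round(ev.t * fps))
        if i + 1 < len(trial.entries):
            f1 = int(round(trial.entries[i + 1].t * fps))
        else:
            f1 = f0 + max(1, int(fps))
        out.append(ChamberEntry(chamber=ev.chamber, entry_frame=f0,
                                exit_frame=max(f1, f0 + 1),
                                trial_idx=trial.trial_idx, with_poke=ev.poked))
    return out


def classify_entries(entries: list[ChamberEntry], *, prev_goal: int | None = None,
                     poke_frames=None, trial: TrialRecord | None = None,
                     fps: float = 30.0,
                     with_poke_known: bool = False) -> list[ChamberEntry]:
    """Set the taxonomy flags on an ordered entry list (in place).

    ``poke_frames`` is a sequence of (frame, port) pairs time-aligned to the
    pose track; alternatively pass ``trial`` to take prev_goal and pokes
    (mapped to frames at ``fps``) from a simulated trial.  With
    ``with_poke_known`` the existing with_poke flags are kept (ground-truth
    logs).
    """
    if trial is not None:
        prev_goal = trial.prev_goal
        if poke_frames is None and not with_poke_known:
            poke_frames = [(int(round(p.t * fps)), p.port) for p in trial.pokes]
    seen: set[int] = set()
    for i, e in enumerate(entries):
        e.duplicate = e.chamber in seen
        seen.add(e.chamber)
        e.prev_reward_return = (prev_goal is not None and e.chamber == prev_goal)
        e.cycling = i > 0 and is_adjacent(e.chamber, entries[i - 1].chamber)
        if not with_poke_known:
            e.with_poke = any(p == e.chamber and e.entry_frame <= f < e.exit_frame
                              for f, p in (poke_frames or []))
    return entries


def entry_rates(trial_entries) -> dict:
    """Session-level per-trial entry-taxonomy means.

    ``trial_entries``: iterable of classified entry lists, one per trial.
    Entries with poke / without poke (checks) and the total exclude
    duplicates and previous-reward returns; p_cycling is over transitions
    that have a defined preceding exit.
    """
    n_trials = 0
    n_dup = 0
    n_prev_trials = 0
    n_cyc = 0
    n_elig = 0
    n_poke = 0
    n_check = 0
    for entries in trial_entries:
        n_trials += 1
        n_dup += sum(e.duplicate for e in entries)
        n_prev_trials += any(e.prev_reward_return for e in entries)
        n_cyc += sum(e.cycling for e in entries[1:])
        n_elig += max(0, len(entries) - 1)
        kept = [e for e in entries if not e.duplicate and not e.prev_reward_return]
        n_poke += sum(e.with_poke for e in kept)
        n_check += sum(not e.with_poke for e in kept)
    if n_trials == 0:
        raise ValueError("need at least one trial")
    return {
        "n_trials": n_trials,
        "duplicates_per_trial": n_dup / n_trials,
        "prev_return_fraction": n_prev_trials / n_trials,
        "p_cycling": n_cyc / n_elig if n_elig else np.nan,
        "entries_with_poke": n_poke / n_trials,
        "entries_without_poke": n_check / n_trials,
        "total_nonexcluded_entries": (n_poke + n_check) / n_trials,
    }


def entries_table(trial_entries_by_trial: dict) -> pd.DataFrame:
    """Tidy entry table: trial, chamber, frames, flags."""
    rows = []
    for trial_idx, entries in trial_entries_by_trial.items():
        for e in entries:
            rows.append({"trial": trial_idx, "chamber": e.chamber,
                         "entry_frame": e.entry_frame, "exit_frame": e.exit_frame,
                         "duplicate": e.duplicate,
                         "prev_reward_return": e.prev_reward_return,
                         "cycling": e.cycling, "with_poke": e.with_poke})
    return pd.DataFrame(rows)


def _segment_metrics(xy: np.ndarray, fps: float) -> tuple[float, float, float, float]:
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    d_actual = float(steps.sum())
    d_straight = float(np.linalg.norm(xy[-1] - xy[0]))
    straightness = d_straight / d_actual if d_actual > 0 else 1.0
    duration = (len(xy) - 1) / fps
    mean_speed = d_actual / duration if duration > 0 else 0.0
    return d_straight, d_actual, straightness, mean_speed


def center_segments(pose: PoseTrack, geom: ArenaGeometry,
                    min_frames: int = MIN_CENTER_FRAMES,
                    part: str = "snout") -> list[PathSegment]:
    """Speed and straightness of paths through the center chamber."""
    xy = _interp_gaps(_snout_cm(pose, geom, part), MAX_INTERP_GAP)
    labels = arena.classify_points(geom, xy)
    segs = []
    for lab, s, e in _label_runs(labels):
        if lab == CENTER and e - s >= min_frames:
            ds, da, st, sp = _segment_metrics(xy[s:e], pose.fps)
            segs.append(PathSegment(start_frame=s, end_frame=e, d_straight=ds,
                                    d_actual=da, straightness=st, mean_speed=sp))
    return segs


def stillness_fractions(pose: PoseTrack, geom: ArenaGeometry,
                        still_threshold_cm_s: float = STILL_THRESHOLD_CM_S,
                        part: str = "snout") -> dict:
    """Fraction of frames with sub-threshold speed, split by region.

    Speeds are frame-to-frame snout displacements times fps (cm/s); each
    speed sample is attributed to the region of its later frame.
    """
    if still_threshold_cm_s <= 0:
        raise ValueError("threshold must be positive")
    xy = _interp_gaps(_snout_cm(pose, geom, part), MAX_INTERP_GAP)
    labels = arena.classify_points(geom, xy)
    speeds = np.linalg.norm(np.diff(xy, axis=0), axis=1) * pose.fps
    lab = labels[1:]
    out = {}
    for name, mask in (("center", lab == CENTER), ("side", lab >= 0)):
        sel = speeds[mask & np.isfinite(speeds)]
        out[f"frac_still_{name}"] = (float(np.mean(sel < still_threshold_cm_s))
                                     if sel.size else np.nan)
    return out
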