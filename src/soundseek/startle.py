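"""Acoustic startle quantification from pose tracks.

The startle reflex is a rapid whole-body muscular contraction to a sudden
loud sound.  It is quantified from video pose tracking as the per-frame
distance moved by each body part (pixels between adjacent frames, averaged
across parts), and summarized per stimulus as the mean movement over the
first five frames (167 ms at 30 fps) after stimulus onset.  Trials at the
two stimulus levels (80 and 90 dB SPL) elicit similar responses and are
pooled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pose import PoseTrack

STARTLE_WINDOW_FRAMES = 5
BASELINE_FRAMES = 15          # 0.5 s at 30 fps, reported for context only
STARTLE_LEVELS_DB = (80, 90)  # pooled in analysis


def window_ms(fps: float, window: int = STARTLE_WINDOW_FRAMES) -> int:
    """Duration of the startle window in ms (rounded): 167 at 30 fps."""
    return round(window / fps * 1000.0)


@dataclass(frozen=True)
class StartleTrial:
    onset_frame: int
    level_db: float
    magnitude: float     # px/frame (or cm/frame for cm-unit tracks)
    baseline: float
    n_missing: int       # missing movement samples inside the window


def frame_movement(pose: PoseTrack) -> np.ndarray:
    """Whole-body movement per frame.

    ``movement[t]`` is the Euclidean displacement from frame t-1 to t of
    each body part, averaged over parts tracked on both frames; index 0
    (and any frame where every part is missing) is NaN.
    """
    if pose.n_frames < 2:
        raise ValueError("need at least two frames")
    disp = np.linalg.norm(np.diff(pose.coords, axis=0), axis=2)  # (frames-1, parts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN frames
        move = np.nanmean(disp, axis=1)
    return np.r_[np.nan, move]


def startle_magnitude(movement: np.ndarray, onset_frame: int,
                      window: int = STARTLE_WINDOW_FRAMES) -> tuple[float, int]:
    """Mean movement over the ``window`` frames starting at the onset frame.

    Returns (magnitude, number of missing samples excluded from the mean).
    """
    if onset_frame < 0 or onset_frame + window > len(movement):
        raise ValueError("startle window out of track bounds")
    vals = movement[onset_frame:onset_frame + window]
    n_missing = int(np.sum(~np.isfinite(vals)))
    if n_missing == window:
        return float("nan"), n_missing
    return float(np.nanmean(vals)), n_missing


def onset_to_frame(onset_s: float, fps: float) -> int:
    """First frame at or after the stimulus onset."""
    return math.ceil(onset_s * fps - 1e-9)


def startle_session(pose: PoseTrack, onsets_s, levels_db=None, *,
                    window: int = STARTLE_WINDOW_FRAMES,
                    baseline_frames: int = BASELINE_FRAMES,
                    align_pre: int = 15, align_post: int = 30) -> dict:
    """Per-trial startle magnitudes plus the onset-aligned average curve.

    Returns a dict with 'trials' (list of StartleTrial), 'session_mean'
    (levels pooled), 'window_ms', and the aligned movement matrix /
    mean / SEM over trials on a frame axis from -align_pre to +align_post.
    """
    onsets_s = np.atleast_1d(np.asarray(onsets_s, dtype=float))
    if onsets_s.size == 0:
        raise ValueError("need at least one stimulus onset")
    if levels_db is None:
        levels_db = np.full(onsets_s.shape, STARTLE_LEVELS_DB[0], dtype=float)
    levels_db = np.atleast_1d(np.asarray(levels_db, dtype=float))

    movement = frame_movement(pose)
    frames = np.array([onset_to_frame(t, pose.fps) for t in onsets_s])
    order = np.argsort(frames)
    if np.any(np.diff(frames[order]) < window):
        warnings.warn("startle windows overlap; trials kept")

    trials = []
    aligned = np.full((len(frames), align_pre + align_post), np.nan)
    rel = np.arange(-align_pre, align_post)
    for i, (f, lv) in enumerate(zip(frames, levels_db)):
        mag, n_miss = startle_magnitude(movement, f, window)
        b0, b1 = max(0, f - baseline_frames), f
        base = float(np.nanmean(movement[b0:b1])) if b1 > b0 else float("nan")
        trials.append(StartleTrial(onset_frame=int(f), level_db=float(lv),
                                   magnitude=mag, baseline=base, n_missing=n_miss))
        idx = f + rel
        ok = (idx >= 0) & (idx < len(movement))
        aligned[i, ok] = movement[idx[ok]]

    mags = np.array([t.magnitude for t in trials])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        curve_mean = np.nanmean(aligned, axis=0)
        n_per = np.sum(np.isfinite(aligned), axis=0)
        curve_sem = np.nanstd(aligned, axis=0, ddof=1) / np.sqrt(np.maximum(n_per, 1))
    return {
        "trials": trials,
        "session_mean": float(np.nanmean(mags)),
        "window_ms": window_ms(pose.fps, window),
        "aligned_frames": rel,
        "aligned": aligned,
        "aligned_mean": curve_mean,
        "aligned_sem": curve_sem,
    }


def trials_table(result: dict) -> pd.DataFrame:
    return pd.DataFrame([{"onset_frame": t.onset_frame, "level_db": t.level_db,
                          "magnitude": t.magnitude, "baseline": t.baseline,
                          "n_missing": t.n_missing} for t in result["trials"]])
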