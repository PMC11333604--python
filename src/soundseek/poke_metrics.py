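"""Trial scoring and learning-curve analytics from poke logs.

Two headline performance metrics, computed after disregarding all pokes
into the previously rewarded port (which can never be the goal) and
duplicate pokes into the same port:

* fraction correct - trials on which the goal was the first counted port;
* ports poked per trial - the goal's position in the ordered list of
  distinct counted ports: 1 on a correct trial, up to 7 when every other
  eligible port was poked first (8 is unreachable because the previously
  rewarded port never counts).

Any sound-independent policy yields 4 ports poked per trial and fraction
correct 1/7 in expectation, because the goal's rank among the 7 eligible
ports is uniform on 1..7.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .task import SessionLog, TrialRecord

CRITERION_PORTS_POKED = 2.5   # "good performance": fewer than this per session
SMOOTHING_SD_TRIALS = 50.0    # Gaussian kernel SD for learning curves


@dataclass(frozen=True)
class TrialScore:
    correct: bool
    ports_poked: int
    n_raw_pokes: int
    trial_idx: int
    session_idx: int = 0


def score_trial(trial: TrialRecord, session_idx: int = 0) -> TrialScore:
    """Score one trial by the disregard-then-rank rules.

    Counted ports are the ordered distinct poked ports excluding the
    previously rewarded one; ports_poked is the goal's 1-based position in
    that list.  Raises on trials that did not end with a goal poke.
    """
    if not trial.complete:
        raise ValueError(f"trial {trial.trial_idx} is incomplete (never poked goal)")
    if not trial.pokes or trial.pokes[-1].port != trial.goal:
        raise ValueError(f"trial {trial.trial_idx} does not end with a goal poke")
    counted: list[int] = []
    for ev in trial.pokes:
        if ev.port == trial.prev_goal or ev.port in counted:
            continue
        counted.append(ev.port)
    pos = counted.index(trial.goal) + 1
    return TrialScore(correct=(pos == 1), ports_poked=pos,
                      n_raw_pokes=len(trial.pokes),
                      trial_idx=trial.trial_idx, session_idx=session_idx)


def score_session(log: SessionLog) -> list[TrialScore]:
    """Scores for all complete trials of a session."""
    return [score_trial(t, session_idx=log.session_idx)
            for t in log.trials if t.complete]


def session_summary(log: SessionLog) -> dict:
    """Per-session means; incomplete trials excluded and counted separately."""
    scores = score_session(log)
    n_inc = sum(not t.complete for t in log.trials)
    if not scores:
        return {"subject": log.subject, "session_idx": log.session_idx,
                "condition": log.condition, "n_trials": 0, "n_incomplete": n_inc,
                "fraction_correct": np.nan, "mean_ports_poked": np.nan}
    return {
        "subject": log.subject,
        "session_idx": log.session_idx,
        "condition": log.condition,
        "n_trials": len(scores),
        "n_incomplete": n_inc,
        "fraction_correct": float(np.mean([s.correct for s in scores])),
        "mean_ports_poked": float(np.mean([s.ports_poked for s in scores])),
    }


def summary_table(logs) -> pd.DataFrame:
    """Tidy per-session summary table over a sequence of SessionLogs."""
    return pd.DataFrame([session_summary(log) for log in logs])


def smooth_by_trial(values, sd_trials: float = SMOOTHING_SD_TRIALS) -> np.ndarray:
    """Gaussian-kernel smoothing over cumulative trial index.

    The kernel is renormalized at the edges (smoothing of ones divides the
    smoothing of the data), so constants pass through unchanged and there
    is no padding bias.  ``sd_trials = 0`` is the identity.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one value")
    if sd_trials <= 0:
        return v.copy()
    num = gaussian_filter1d(v, sd_trials, mode="constant", cval=0.0, truncate=6.0)
    den = gaussian_filter1d(np.ones_like(v), sd_trials, mode="constant",
                            cval=0.0, truncate=6.0)
    return num / den


def find_criterion(mean_ports_poked_by_session,
                   threshold: float = CRITERION_PORTS_POKED) -> int | None:
    """First session index performing better (strictly fewer ports poked)
    than the criterion, or None if never reached.

    Assessed on raw per-session means, not smoothed curves.
    """
    for i, m in enumerate(mean_ports_poked_by_session):
        if m < threshold:
            return i
    return None
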