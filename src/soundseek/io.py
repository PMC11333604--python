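"""Tidy-CSV readers and writers for session logs.

A session is written as a bundle of three CSVs sharing a path prefix:
``<prefix>_trials.csv`` (one row per trial, with the stimulus parameters),
``<prefix>_pokes.csv`` (one row per poke) and ``<prefix>_entries.csv``
(one row per simulated chamber entry).  Round-trips are exact up to float
representation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .stimulus import StimulusParams
from .task import EntryEvent, PokeEvent, SessionLog, TrialRecord

_STIM_COLS = ("rep_rate_hz", "irregularity_ms", "center_freq_khz",
              "level_db", "bandwidth_khz", "burst_dur_ms")


def session_tables(log: SessionLog) -> dict[str, pd.DataFrame]:
    trial_rows, poke_rows, entry_rows = [], [], []
    for tr in log.trials:
        row = {"subject": log.subject, "session_idx": log.session_idx,
               "condition": log.condition, "trial": tr.trial_idx,
               "goal": tr.goal,
               "prev_goal": -1 if tr.prev_goal is None else tr.prev_goal,
               "reward_t": np.nan if tr.reward_t is None else tr.reward_t,
               "complete": tr.complete}
        row.update({c: getattr(tr.stim, c) for c in _STIM_COLS})
        trial_rows.append(row)
        for p in tr.pokes:
            poke_rows.append({"subject": log.subject, "session_idx": log.session_idx,
                              "trial": tr.trial_idx, "t": p.t, "port": p.port,
                              "rewarded": tr.complete and p is tr.pokes[-1]
                              and p.port == tr.goal})
        for e in tr.entries:
            entry_rows.append({"subject": log.subject, "session_idx": log.session_idx,
                               "trial": tr.trial_idx, "t": e.t,
                               "chamber": e.chamber, "poked": e.poked})
    return {"trials": pd.DataFrame(trial_rows),
            "pokes": pd.DataFrame(poke_rows),
            "entries": pd.DataFrame(entry_rows)}


def write_session(log: SessionLog, prefix) -> list[Path]:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in session_tables(log).items():
        p = prefix.parent / f"{prefix.name}_{name}.csv"
        df.to_csv(p, index=False)
        paths.append(p)
    return paths


def read_session(prefix) -> SessionLog:
    prefix = Path(prefix)
    trials_df = pd.read_csv(prefix.parent / f"{prefix.name}_trials.csv", float_precision="round_trip")
    pokes_df = pd.read_csv(prefix.parent / f"{prefix.name}_pokes.csv", float_precision="round_trip")
    entries_df = pd.read_csv(prefix.parent / f"{prefix.name}_entries.csv", float_precision="round_trip")
    pokes_by_trial = dict(tuple(pokes_df.groupby("trial"))) if len(pokes_df) else {}
    entries_by_trial = dict(tuple(entries_df.groupby("trial"))) if len(entries_df) else {}

    trials = []
    for _, row in trials_df.iterrows():
        stim = StimulusParams(**{c: float(row[c]) for c in _STIM_COLS})
        pk = pokes_by_trial.get(row["trial"])
        pokes = ([PokeEvent(t=float(r.t), port=int(r.port))
                  for r in pk.itertuples()] if pk is not None else [])
        en = entries_by_trial.get(row["trial"])
        entries = ([EntryEvent(t=float(r.t), chamber=int(r.chamber), poked=bool(r.poked))
                    for r in en.itertuples()] if en is not None else [])
        trials.append(TrialRecord(
            trial_idx=int(row["trial"]), goal=int(row["goal"]),
            prev_goal=None if row["prev_goal"] < 0 else int(row["prev_goal"]),
            pokes=pokes, entries=entries,
            reward_t=None if pd.isna(row["reward_t"]) else float(row["reward_t"]),
            stim=stim, complete=bool(row["complete"])))
    first = trials_df.iloc[0]
    duration = max((t.reward_t for t in trials if t.reward_t is not None), default=0.0)
    return SessionLog(subject=str(first["subject"]), session_idx=int(first["session_idx"]),
                      condition=str(first["condition"]), trials=trials,
                      duration_s=float(duration) + 1.0)
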