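"""The sound-seeking trial state machine.

On each trial one of the eight speakers (the goal) plays an ongoing sound
stream; the goal is drawn uniformly but never repeats on consecutive
trials.  The trial runs until the agent pokes the goal port; pokes into
other ports trigger an error sound but do not end the trial.  The next
trial begins 1 s after reward.

Time is simulated in abstract action ticks (one tick per agent action,
``action_dur`` seconds each); behavioral metrics never depend on absolute
time except inter-trial bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arena import CENTER, N_PORTS
from .stimulus import StimulusParams, fixed_params, sample_variable_params

#: Default cap on agent actions per trial; trials hitting it are flagged
#: incomplete and excluded from scoring (the real task has no unfinished trials).
MAX_ACTIONS = 200

ITI_S = 1.0  # next trial begins 1 s after the previous reward


class IllegalActionError(RuntimeError):
    """An agent emitted an action that is illegal in its current region."""


@dataclass(frozen=True)
class Observation:
    """What the agent may condition on at each step."""
    region: int            # current chamber 0..7 or CENTER
    audible: bool          # sound cue available (inside the goal chamber)
    visited: frozenset     # chambers entered so far this trial
    prev_goal: int | None


@dataclass(frozen=True)
class PokeEvent:
    t: float
    port: int


@dataclass
class EntryEvent:
    """A chamber visit in the simulated event log (ground-truth entries)."""
    t: float
    chamber: int
    poked: bool = False


@dataclass
class TrialRecord:
    trial_idx: int
    goal: int
    prev_goal: int | None
    pokes: list            # of PokeEvent, in time order
    entries: list          # of EntryEvent, in time order
    reward_t: float | None
    stim: StimulusParams
    complete: bool = True


@dataclass
class SessionLog:
    subject: str
    session_idx: int
    condition: str         # pre | sham | unilateral | bilateral (+ post-op day)
    trials: list
    duration_s: float


def draw_goal(prev_goal: int | None, rng) -> int:
    """Uniform over the 7 ports != prev_goal (all 8 on the first trial)."""
    if prev_goal is None:
        return int(rng.integers(N_PORTS))
    k = int(rng.integers(N_PORTS - 1))
    return k if k < prev_goal else k + 1


def run_trial(policy, goal: int, prev_goal: int | None, rng, *,
              stim: StimulusParams | None = None, trial_idx: int = 0,
              t0: float = 0.0, action_dur: float = 1.0,
              max_actions: int = MAX_ACTIONS) -> TrialRecord:
    """Run one trial: the agent acts until it pokes the goal port.

    The agent starts physically inside the previously rewarded chamber
    (a random chamber on the first trial).  Legal actions are
    ``('enter', k)`` from the center, ``('leave', None)`` and
    ``('poke', None)`` from inside a chamber.
    """
    stim = fixed_params() if stim is None else stim
    start = prev_goal if prev_goal is not None else int(rng.integers(N_PORTS))
    policy.begin_trial(goal=goal, prev_goal=prev_goal, start_chamber=start, rng=rng)

    region = start
    visited: set[int] = set()
    pokes: list[PokeEvent] = []
    entries: list[EntryEvent] = []
    t = t0
    rewarded = False

    for _ in range(max_actions):
        obs = Observation(region=region, audible=(region == goal),
                          visited=frozenset(visited), prev_goal=prev_goal)
        action, arg = policy.step(obs)
        t += action_dur
        if action == "enter":
            if region != CENTER:
                raise IllegalActionError("enter is only legal from the center")
            if not (0 <= arg < N_PORTS):
                raise IllegalActionError(f"no chamber {arg}")
            region = int(arg)
            visited.add(region)
            entries.append(EntryEvent(t=t, chamber=region))
        elif action == "leave":
            if region == CENTER:
                raise IllegalActionError("leave is only legal from a chamber")
            region = CENTER
        elif action == "poke":
            if region == CENTER:
                raise IllegalActionError("poke is only legal from a chamber")
            pokes.append(PokeEvent(t=t, port=region))
            if entries and entries[-1].chamber == region:
                entries[-1].poked = True
            if region == goal:
                rewarded = True
                break
        else:
            raise IllegalActionError(f"unknown action {action!r}")

    return TrialRecord(trial_idx=trial_idx, goal=goal, prev_goal=prev_goal,
                       pokes=pokes, entries=entries,
                       reward_t=t if rewarded else None,
                       stim=stim, complete=rewarded)


def run_session(policy, n_trials: int, *, condition: str = "pre",
                seed=None, rng=None, subject: str = "sim", session_idx: int = 0,
                stim_mode: str = "fixed", iti_s: float = ITI_S,
                action_dur: float = 1.0, max_actions: int = MAX_ACTIONS) -> SessionLog:
    """Sequential trials under the no-repeat goal rule; seeded, reproducible.

    ``prev_goal`` resets to None at the start of every session (whether the
    previous session's last goal carries over is an open point of the real
    task; resetting is the conservative choice).
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    trials = []
    prev: int | None = None
    t = 0.0
    for i in range(n_trials):
        goal = draw_goal(prev, rng)
        stim = fixed_params() if stim_mode == "fixed" else sample_variable_params(rng)
        tr = run_trial(policy, goal, prev, rng, stim=stim, trial_idx=i, t0=t,
                       action_dur=action_dur, max_actions=max_actions)
        trials.append(tr)
        t = (tr.reward_t if tr.complete else t + max_actions * action_dur) + iti_s
        prev = goal
    return SessionLog(subject=subject, session_idx=session_idx,
                      condition=condition, trials=trials, duration_s=t)
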