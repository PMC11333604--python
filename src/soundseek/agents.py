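"""Synthetic-mouse policies for the sound-seeking task.

Each agent is a per-trial mixture of four strategy components:

``random``
    sound-independent: from the center, enter a uniformly random chamber
    other than the one just exited, and poke its port.
``cycle``
    traplining: visit chambers in ring order (cw or ccw) starting from the
    previously rewarded chamber, poking each port in turn.
``direct``
    sound-guided: with probability ``p_direct`` head straight to the goal
    chamber; otherwise mis-localize to a silent, not-yet-poked chamber.
    Pokes wherever it goes.
``check``
    sweep chambers in ring order but sample each one for sound before
    committing: poke with ``p_poke_given_goal`` when the goal's stream is
    audible (i.e. inside the goal chamber) and with ``p_poke_given_nongoal``
    otherwise, else leave without poking (a "check").

One component is drawn per trial.  Agents start each trial in the
previously rewarded chamber (where the animal physically is after
consuming reward) and may first revisit it with probability
``p_return_prev``.  Strategy components receive the goal identity at trial
start but are bound to use it only through their cue model: ``direct``
exploits it with probability ``p_direct`` (binaural localization from the
center), ``check`` only via the in-chamber audibility flag (monaural
sampling); ``random`` and ``cycle`` never use it.

Presets span the study conditions: naive and expert behavior, and the
post-surgery phenotypes (sham unchanged; bilateral loss -> routinized
cycling with a poke at every port, i.e. chance-level exhaustive search;
unilateral loss -> recovery via checking each chamber for sound).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .arena import CENTER, N_PORTS

COMPONENTS = ("random", "cycle", "direct", "check")


@dataclass(frozen=True)
class AgentConfig:
    """Strategy mixture weights and per-component parameters."""
    w_random: float = 1.0
    w_cycle: float = 0.0
    w_direct: float = 0.0
    w_check: float = 0.0
    p_direct: float = 0.5            # P(sound-guided move hits the goal chamber)
    cycle_direction: str = "random"  # 'cw' | 'ccw' | 'random' (per trial)
    p_poke_given_goal: float = 1.0   # checker pokes an audible chamber
    p_poke_given_nongoal: float = 0.0  # checker falsely pokes a silent chamber
    p_return_prev: float = 0.0       # revisit the previously rewarded chamber first

    def weights(self) -> np.ndarray:
        w = np.array([self.w_random, self.w_cycle, self.w_direct, self.w_check],
                     dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("mixture weights must be nonnegative and sum > 0")
        return w / w.sum()

    def validate(self) -> None:
        for name in ("p_direct", "p_poke_given_goal", "p_poke_given_nongoal",
                     "p_return_prev"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.cycle_direction not in ("cw", "ccw", "random"):
            raise ValueError(f"bad cycle_direction {self.cycle_direction!r}")
        self.weights()


class MixtureAgent:
    """Per-trial strategy-mixture policy implementing the task protocol."""

    def __init__(self, config: AgentConfig):
        config.validate()
        self.config = config

    def begin_trial(self, *, goal: int, prev_goal: int | None,
                    start_chamber: int, rng) -> None:
        c = self.config
        self._rng = rng
        self._goal = goal
        self._prev = prev_goal
        self._component = COMPONENTS[int(rng.choice(len(COMPONENTS), p=c.weights()))]
        if c.cycle_direction == "random":
            self._dir = 1 if rng.random() < 0.5 else -1
        else:
            self._dir = 1 if c.cycle_direction == "ccw" else -1
        self._last_chamber = start_chamber
        self._poked: set[int] = set()
        self._just_poked = False
        self._at_start = True
        self._pending_return = (prev_goal is not None
                                and rng.random() < c.p_return_prev)

    # -- poke decision inside a chamber -------------------------------------

    def _wants_poke(self, region: int, audible: bool) -> bool:
        c = self.config
        if self._component == "check":
            p = c.p_poke_given_goal if audible else c.p_poke_given_nongoal
            return bool(self._rng.random() < p)
        # random / cycle / direct components poke wherever they go
        return True

    # -- chamber choice from the center --------------------------------------

    def _next_chamber(self) -> int:
        rng, c = self._rng, self.config
        if self._pending_return:
            self._pending_return = False
            return self._prev
        if self._component in ("cycle", "check"):
            return (self._last_chamber + self._dir) % N_PORTS
        if self._component == "direct":
            if rng.random() < c.p_direct:
                return self._goal
            wrong = [k for k in range(N_PORTS)
                     if k != self._goal and k != self._prev and k not in self._poked]
            if not wrong:
                return self._goal
            return int(wrong[rng.integers(len(wrong))])
        # random: uniform over the 7 chambers other than the one just exited
        k = int(rng.integers(N_PORTS - 1))
        return k if k < self._last_chamber else k + 1

    def step(self, obs) -> tuple[str, int | None]:
        if obs.region == CENTER:
            self._just_poked = False
            return ("enter", self._next_chamber())
        if self._at_start:
            # the trial starts with the agent still inside the previously
            # rewarded chamber; it heads out rather than poking again
            self._at_start = False
            self._last_chamber = obs.region
            return ("leave", None)
        # inside a chamber: poke at most once per visit, then leave
        if not self._just_poked and self._wants_poke(obs.region, obs.audible):
            self._just_poked = True
            self._poked.add(obs.region)
            return ("poke", None)
        self._just_poked = False
        self._last_chamber = obs.region
        return ("leave", None)


#: Illustrative generator settings for the study conditions.  These are
#: synthetic-data choices (the real strategy mixtures were never fitted):
#: the expert p_direct = 0.55 puts the truncated-geometric mean of the
#: direct policy at ~1.8 ports poked per trial, the observed expert
#: plateau; the bilateral preset (cycle poking every port) sits exactly at
#: the chance level of 4; the unilateral presets recover via checking.
PRESETS = {
    "naive": AgentConfig(w_random=1.0, p_return_prev=0.3),
    "expert": AgentConfig(w_random=0.0, w_direct=1.0, p_direct=0.55,
                          p_return_prev=0.05),
    "sham_post": AgentConfig(w_random=0.0, w_direct=1.0, p_direct=0.5,
                             p_return_prev=0.05),
    "unilateral_early": AgentConfig(w_random=0.3, w_cycle=0.4, w_direct=0.0,
                                    w_check=0.3, p_poke_given_nongoal=0.5,
                                    p_return_prev=0.1),
    "unilateral_recovered": AgentConfig(w_random=0.0, w_direct=0.2, w_check=0.8,
                                        p_direct=0.5, p_poke_given_nongoal=0.05,
                                        p_return_prev=0.05),
    "bilateral_post": AgentConfig(w_random=0.0, w_cycle=1.0, p_return_prev=0.0),
}


def scenario_presets(name: str) -> AgentConfig:
    """AgentConfig for a named study condition (see PRESETS)."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")


def make_agent(preset_or_config) -> MixtureAgent:
    if isinstance(preset_or_config, str):
        return MixtureAgent(scenario_presets(preset_or_config))
    return MixtureAgent(preset_or_config)
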