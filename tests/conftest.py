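import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from soundseek.arena import CENTER, build_geometry

settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def geom():
    return build_geometry()


class ScriptedAgent:
    """Test double: pokes a fixed port sequence, one visit per poke."""

    def __init__(self, ports):
        self.ports = list(ports)

    def begin_trial(self, *, goal, prev_goal, start_chamber, rng):
        self.queue = list(self.ports)
        self._at_start = True
        self._poked = False

    def step(self, obs):
        if obs.region == CENTER:
            self._poked = False
            return ("enter", self.queue.pop(0))
        if self._at_start:
            self._at_start = False
            return ("leave", None)
        if not self._poked:
            self._poked = True
            return ("poke", None)
        return ("leave", None)


class NeverPokeAgent:
    """Test double: wanders without ever poking (incomplete trials)."""

    def begin_trial(self, *, goal, prev_goal, start_chamber, rng):
        self._rng = rng
        self._at_start = True

    def step(self, obs):
        if obs.region == CENTER:
            return ("enter", int(self._rng.integers(8)))
        return ("leave", None)


@pytest.fixture
def scripted_agent():
    return ScriptedAgent


@pytest.fixture
def never_poke_agent():
    return NeverPokeAgent
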