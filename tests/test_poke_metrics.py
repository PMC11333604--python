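"""Trial scoring by the disregard rules, summaries, smoothing, criterion."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from soundseek.poke_metrics import (find_criterion, score_trial, session_summary,
                                    smooth_by_trial)
from soundseek.stimulus import fixed_params
from soundseek.task import PokeEvent, SessionLog, TrialRecord


def make_trial(goal, prev_goal, ports, trial_idx=0, complete=True):
    pokes = [PokeEvent(t=float(i + 1), port=p) for i, p in enumerate(ports)]
    return TrialRecord(trial_idx=trial_idx, goal=goal, prev_goal=prev_goal,
                       pokes=pokes, entries=[],
                       reward_t=float(len(ports)) if complete else None,
                       stim=fixed_params(), complete=complete)


@pytest.mark.parametrize("goal,prev,ports,expected_pp,expected_correct", [
    (3, 2, [2, 5, 5, 3], 2, False),     # prev poke and duplicate disregarded
    (3, 2, [3], 1, True),
    (3, 2, [0, 1, 4, 5, 6, 7, 3], 7, False),  # every eligible port first
    (3, 2, [2, 2, 2, 3], 1, True),      # only prev pokes before the goal
    (0, None, [5, 0], 2, False),        # first trial of a session: all 8 count
])
def test_score_trial_examples(goal, prev, ports, expected_pp, expected_correct):
    s = score_trial(make_trial(goal, prev, ports))
    assert s.ports_poked == expected_pp
    assert s.correct is expected_correct
    assert s.n_raw_pokes == len(ports)


def test_score_trial_rejects_bad_trials():
    with pytest.raises(ValueError):
        score_trial(make_trial(3, 2, [3, 5]))  # does not end at goal
    with pytest.raises(ValueError):
        score_trial(make_trial(3, 2, [5], complete=False))


@given(st.data())
def test_ports_poked_capped_at_seven(data):
    """Random poke sequences never score 8: the previously rewarded port
    never counts."""
    prev = data.draw(st.integers(0, 7))
    goal = data.draw(st.integers(0, 7).filter(lambda g: g != prev))
    body = data.draw(st.lists(st.integers(0, 7).filter(lambda p: p != goal),
                              max_size=30))
    s = score_trial(make_trial(goal, prev, body + [goal]))
    assert 1 <= s.ports_poked <= 7


@given(st.data())
def test_score_invariant_to_duplicates_and_prev_insertions(data):
    prev = data.draw(st.integers(0, 7))
    goal = data.draw(st.integers(0, 7).filter(lambda g: g != prev))
    body = data.draw(st.lists(
        st.integers(0, 7).filter(lambda p: p not in (goal, prev)),
        unique=True, max_size=6))
    base = score_trial(make_trial(goal, prev, body + [goal]))
    # splice prev pokes and duplicates of already-poked ports anywhere
    noisy = []
    for i, p in enumerate(body):
        noisy += [prev, p, p] if i % 2 == 0 else [p, prev]
    noisy += [prev, goal]
    s = score_trial(make_trial(goal, prev, noisy))
    assert (s.ports_poked, s.correct) == (base.ports_poked, base.correct)


def _session(trials):
    return SessionLog(subject="m0", session_idx=0, condition="pre",
                      trials=trials, duration_s=100.0)


def test_session_summary_arithmetic():
    trials = [make_trial(3, 2, [3], 0), make_trial(5, 3, [5], 1),
              make_trial(1, 5, [0, 2, 4, 1], 2)]
    s = session_summary(_session(trials))
    assert s["mean_ports_poked"] == pytest.approx(2.0)
    assert s["fraction_correct"] == pytest.approx(2 / 3)
    assert s["n_trials"] == 3 and s["n_incomplete"] == 0


def test_session_summary_all_correct_and_empty():
    trials = [make_trial((i + 1) % 8, i % 8, [(i + 1) % 8], i) for i in range(5)]
    s = session_summary(_session(trials))
    assert (s["fraction_correct"], s["mean_ports_poked"]) == (1.0, 1.0)
    empty = session_summary(_session([make_trial(3, 2, [5], complete=False)]))
    assert empty["n_trials"] == 0 and empty["n_incomplete"] == 1
    assert np.isnan(empty["fraction_correct"])


def test_smoothing_constant_passthrough():
    out = smooth_by_trial(np.full(300, 3.7), sd_trials=50)
    assert np.allclose(out, 3.7)


def test_smoothing_impulse_matches_analytic_kernel():
    n = 1001
    x = np.zeros(n)
    x[500] = 1.0
    out = smooth_by_trial(x, sd_trials=50)
    idx = np.arange(n)
    kern = np.exp(-0.5 * ((idx - 500) / 50.0) ** 2)
    kern /= kern.sum()
    assert np.allclose(out, kern, atol=1e-6)


def test_smoothing_zero_sd_identity_and_length():
    x = np.array([1.0, 4.0, 2.0])
    assert np.array_equal(smooth_by_trial(x, sd_trials=0), x)
    assert len(smooth_by_trial(np.arange(10.0), 50)) == 10
    with pytest.raises(ValueError):
        smooth_by_trial([])


@pytest.mark.parametrize("means,expected", [
    ([3.5, 2.6, 2.4, 2.0], 2),
    ([3.0, 2.5, 2.6], None),      # strict inequality: 2.5 is not better
    ([2.4, 3.0, 2.0], 0),         # first crossing only, no persistence
    ([], None),
])
def test_find_criterion(means, expected):
    assert find_criterion(means) == expected
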