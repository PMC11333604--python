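"""Entry detection, taxonomy flags, center-path and stillness metrics."""

import numpy as np
import pytest

from soundseek import entry_metrics as em
from soundseek.agents import AgentConfig, MixtureAgent
from soundseek.arena import CENTER
from soundseek.entry_metrics import (ChamberEntry, center_segments,
                                     classify_entries, detect_entries,
                                     entries_from_trial, entry_rates,
                                     stillness_fractions)
from soundseek.pose import DEFAULT_PARTS, PoseTrack
from soundseek.poke_metrics import score_trial
from soundseek.synth import random_entry_sequence, synth_trajectory
from soundseek.task import run_session


def snout_track(xy, fps=30.0):
    """Pose track whose every body part sits on the given snout path."""
    xy = np.asarray(xy, dtype=float)
    coords = np.repeat(xy[:, None, :], len(DEFAULT_PARTS), axis=1)
    return PoseTrack(fps=fps, body_parts=DEFAULT_PARTS, coords=coords)


# -- detection ----------------------------------------------------------------

def test_detect_entries_round_trip(geom):
    rng = np.random.default_rng(50)
    for i in range(10):
        seq = random_entry_sequence(rng, int(rng.integers(1, 8)))
        track = synth_trajectory(seq, geom, jitter_cm=0.2, seed=100 + i)
        ents = detect_entries(track, geom)
        assert [e.chamber for e in ents] == [k for k, _ in seq]
        classify_entries(ents, prev_goal=None,
                         poke_frames=track.meta["poke_frames"])
        assert [e.with_poke for e in ents] == [p for _, p in seq]


def test_boundary_graze_debounced(geom):
    center = np.zeros(2)
    anchor = np.asarray(geom.chamber_polygons[2].centroid.coords[0])
    xy = np.vstack([np.tile(center, (10, 1)), anchor, np.tile(center, (10, 1))])
    assert detect_entries(snout_track(xy), geom, debounce_frames=2) == []


def test_no_entries_when_staying_in_center(geom):
    xy = np.tile(np.zeros(2), (60, 1))
    assert detect_entries(snout_track(xy), geom) == []


def test_detect_entries_requires_snout(geom):
    xy = np.full((30, 2), np.nan)
    with pytest.raises(ValueError):
        detect_entries(snout_track(xy), geom)


def test_missing_gap_interpolated(geom):
    seq = [(1, True), (4, False)]
    track = synth_trajectory(seq, geom, jitter_cm=0.05, seed=9)
    si = track.body_parts.index("snout")
    track.coords[20:24, si, :] = np.nan  # 4-frame gap: interpolated
    ents = detect_entries(track, geom)
    assert [e.chamber for e in ents] == [1, 4]


# -- taxonomy -----------------------------------------------------------------

def _entries(chambers):
    return [ChamberEntry(chamber=c, entry_frame=10 * i, exit_frame=10 * i + 5)
            for i, c in enumerate(chambers)]


def test_duplicate_flag():
    ents = classify_entries(_entries([1, 2, 1]), prev_goal=None, poke_frames=[])
    assert [e.duplicate for e in ents] == [False, False, True]


def test_cycling_flag_uses_ring_adjacency():
    ents = classify_entries(_entries([2, 3, 5, 4]), prev_goal=None, poke_frames=[])
    assert [e.cycling for e in ents] == [False, True, False, True]


def test_prev_reward_and_check_flags():
    ents = classify_entries(_entries([6, 3]), prev_goal=6,
                            poke_frames=[(12, 3)])
    assert [e.prev_reward_return for e in ents] == [True, False]
    assert [e.with_poke for e in ents] == [False, True]  # poke frame in [10, 15)


def test_entry_rates_partition():
    """Every non-excluded entry is exactly one of with-poke / check."""
    ents = classify_entries(_entries([1, 2, 2, 5]), prev_goal=5,
                            poke_frames=[(1, 1), (11, 2)])
    r = entry_rates([ents])
    assert r["total_nonexcluded_entries"] == (r["entries_with_poke"]
                                              + r["entries_without_poke"])
    assert r["total_nonexcluded_entries"] == 2  # dup 2 and prev-return 5 excluded


def test_entry_rates_requires_trials():
    with pytest.raises(ValueError):
        entry_rates([])


def test_entries_with_poke_matches_ports_poked():
    """Cross-module consistency: when every poke happens inside its chamber,
    the per-trial non-excluded entries-with-poke count equals ports poked."""
    log = run_session(MixtureAgent(AgentConfig(w_random=1.0)), 500, seed=77)
    for t in log.trials:
        ents = classify_entries(entries_from_trial(t), trial=t,
                                with_poke_known=True)
        n_poke = sum(e.with_poke for e in ents
                     if not e.duplicate and not e.prev_reward_return)
        assert n_poke == score_trial(t).ports_poked


# -- center paths -------------------------------------------------------------

def test_straight_crossing(geom):
    v = 18.0  # cm/s
    fps = 30.0
    xs = np.arange(-5.0, 5.0, v / fps)
    xy = np.c_[xs, np.zeros_like(xs)]
    segs = center_segments(snout_track(xy, fps), geom)
    assert len(segs) == 1
    assert segs[0].straightness == pytest.approx(1.0, abs=1e-9)
    assert segs[0].mean_speed == pytest.approx(v, rel=1e-9)
    assert segs[0].d_actual >= segs[0].d_straight


def test_out_and_back_near_zero_straightness(geom):
    xs = np.r_[np.linspace(0, 5, 40), np.linspace(5, 0.01, 40)]
    xy = np.c_[xs, np.zeros_like(xs)]
    segs = center_segments(snout_track(xy), geom)
    assert len(segs) == 1 and segs[0].straightness < 0.05


def test_semicircle_straightness(geom):
    theta = np.linspace(0, np.pi, 2000)
    xy = np.c_[3 * np.cos(theta), 3 * np.sin(theta) - 1.5]
    segs = center_segments(snout_track(xy), geom)
    assert len(segs) == 1
    assert segs[0].straightness == pytest.approx(2 / np.pi, abs=0.02)


def test_straightness_rigid_motion_invariance(geom):
    rng = np.random.default_rng(3)
    steps = rng.normal(0, 0.2, size=(80, 2))
    xy = np.cumsum(steps, axis=0)
    xy -= xy.mean(axis=0)  # keep inside the center region
    base = center_segments(snout_track(xy), geom)[0].straightness
    ang = 0.7
    rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    for trans in ((0.0, 0.0), (0.5, -0.3)):
        moved = xy @ rot.T + np.asarray(trans)
        assert center_segments(snout_track(moved), geom)[0].straightness == \
            pytest.approx(base, abs=1e-9)
    scaled = 0.8 * xy
    assert center_segments(snout_track(scaled), geom)[0].straightness == \
        pytest.approx(base, abs=1e-9)


# -- stillness ----------------------------------------------------------------

def test_stillness_extremes(geom):
    anchor = np.asarray(geom.chamber_polygons[0].centroid.coords[0])
    frozen = np.vstack([np.tile(np.zeros(2), (50, 1)), np.tile(anchor, (50, 1))])
    r = stillness_fractions(snout_track(frozen), geom)
    # the single center->chamber jump is one fast side-chamber sample
    assert r["frac_still_center"] == pytest.approx(1.0)
    assert r["frac_still_side"] == pytest.approx(49 / 50)

    fast = np.c_[np.linspace(-5, 5, 60), np.zeros(60)]  # ~50 cm/s
    r = stillness_fractions(snout_track(fast), geom)
    assert r["frac_still_center"] == 0.0


def test_stillness_constructed_mixture(geom):
    """Recovers per-region still fractions built into the track."""
    anchor = np.asarray(geom.chamber_polygons[3].centroid.coords[0])
    # center phase: 100 frames, first 39 steps zig-zag at 6 cm/s, rest still
    steps = np.zeros((99, 2))
    steps[:39, 0] = 0.2 * (-1.0) ** (np.arange(39) // 10)
    center_xy = np.cumsum(np.vstack([np.zeros(2), steps]), axis=0)
    # side phase: 100 frozen frames at the chamber anchor
    side_xy = np.tile(anchor, (100, 1))
    xy = np.vstack([center_xy, side_xy])
    r = stillness_fractions(snout_track(xy), geom, still_threshold_cm_s=0.5)
    assert r["frac_still_center"] == pytest.approx(60 / 99, abs=0.005)
    assert r["frac_still_side"] == pytest.approx(99 / 100, abs=0.005)

    with pytest.raises(ValueError):
        stillness_fractions(snout_track(xy), geom, still_threshold_cm_s=0)
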