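"""Synthetic-data generators: arena trajectories, startle tracks, ABR epochs.

These generators close the loop for testing: every analysis module in the
package can be run against data whose ground truth is known by
construction.  All generators are reproducible under a seed and stamp
their parameters into the output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arena import ArenaGeometry
from .pose import DEFAULT_PARTS, PoseTrack

# small fixed body-part offsets from the snout (cm); the body moves as a
# rigid-ish cloud, which is all downstream metrics need (they use the snout
# or the mean per-part displacement)
_PART_OFFSETS = {
    "snout": (0.0, 0.0), "head": (-0.8, 0.0),
    "left_fore": (-1.2, 0.5), "right_fore": (-1.2, -0.5),
    "left_hind": (-2.2, 0.6), "right_hind": (-2.2, -0.6),
    "trunk": (-1.8, 0.0), "tail": (-3.0, 0.0),
}


# -- arena trajectories -------------------------------------------------------

def _chamber_anchor(geom: ArenaGeometry, k: int) -> np.ndarray:
    c = geom.chamber_polygons[k].centroid
    return np.array([c.x, c.y])


def _port_approach(geom: ArenaGeometry, k: int, inset_cm: float = 1.5) -> np.ndarray:
    p = geom.port_positions[k]
    return p - inset_cm * p / np.linalg.norm(p)


def synth_trajectory(entries, geom: ArenaGeometry, *, speed_cm_s: float = 20.0,
                     jitter_cm: float = 0.1, fps: float = 30.0, seed=None,
                     chamber_dwell_s: float = 0.25, center_dwell_s: float = 0.2,
                     dropout: float = 0.0) -> PoseTrack:
    """Continuous snout trajectory realizing a chamber-entry sequence.

    ``entries`` is a sequence of ``(chamber, poke_flag)`` pairs; the path
    starts in the center, visits each chamber in order (dwelling at the
    port iff the poke flag is set) and returns through the center between
    visits, as the arena topology forces.  Waypoints are joined by
    constant-speed piecewise-linear motion (splines can overshoot chamber
    boundaries), with i.i.d. Gaussian positional jitter on every
    part-frame.  Poke times are stamped into ``meta['poke_frames']``.
    """
    entries = [(int(k), bool(p)) for k, p in entries]
    for k, _ in entries:
        if not 0 <= k < geom.n_ports:
            raise ValueError(f"no chamber {k}")
    rng = np.random.default_rng(seed)
    center = np.zeros(2)

    # waypoint list: (point, dwell seconds, poke_port_or_None)
    wps: list[tuple[np.ndarray, float, int | None]] = [(center, center_dwell_s, None)]
    for k, poke in entries:
        anchor = _chamber_anchor(geom, k)
        wps.append((anchor, chamber_dwell_s, None))
        if poke:
            wps.append((_port_approach(geom, k), chamber_dwell_s, k))
            wps.append((anchor, 0.0, None))
        wps.append((center, center_dwell_s, None))

    knot_t, knot_xy, poke_times = [0.0], [wps[0][0]], []
    t = wps[0][1]
    knot_t.append(t)
    knot_xy.append(wps[0][0])
    for point, dwell, poke_port in wps[1:]:
        travel = float(np.linalg.norm(point - knot_xy[-1])) / speed_cm_s
        t += travel
        knot_t.append(t)
        knot_xy.append(point)
        if poke_port is not None:
            poke_times.append((t + dwell / 2.0, poke_port))
        if dwell > 0:
            t += dwell
            knot_t.append(t)
            knot_xy.append(point)
    knot_t = np.asarray(knot_t)
    knot_xy = np.asarray(knot_xy)

    n_frames = int(np.ceil(t * fps)) + 1
    ft = np.arange(n_frames) / fps
    snout = np.c_[np.interp(ft, knot_t, knot_xy[:, 0]),
                  np.interp(ft, knot_t, knot_xy[:, 1])]

    parts = DEFAULT_PARTS
    coords = np.empty((n_frames, len(parts), 2))
    for i, name in enumerate(parts):
        coords[:, i, :] = snout + np.asarray(_PART_OFFSETS[name])
    coords += rng.normal(0.0, jitter_cm, size=coords.shape)
    if dropout > 0:
        mask = rng.random((n_frames, len(parts))) < dropout
        coords[mask] = np.nan

    meta = {"entries": entries, "seed": seed, "speed_cm_s": speed_cm_s,
            "jitter_cm": jitter_cm, "dropout": dropout,
            "poke_frames": [(int(round(pt * fps)), port) for pt, port in poke_times]}
    return PoseTrack(fps=fps, body_parts=parts, coords=coords, units="cm", meta=meta)


def random_entry_sequence(rng, n_entries: int, n_ports: int = 8,
                          p_poke: float = 0.5) -> list[tuple[int, bool]]:
    """A random legal entry sequence (any chamber order is legal: the path
    passes through the center between any two chamber visits)."""
    return [(int(rng.integers(n_ports)), bool(rng.random() < p_poke))
            for _ in range(n_entries)]


# -- startle-chamber tracks ---------------------------------------------------

def synth_startle_track(n_frames: int, onsets, startle_gain: float, *,
                        baseline_motion: float = 0.0, fps: float = 30.0,
                        seed=None, dropout: float = 0.0,
                        start_xy=(320.0, 240.0)) -> PoseTrack:
    """Pose track with gain-scaled startle impulses on a baseline wander.

    All body parts are displaced by ``startle_gain`` px on each of the 5
    frames after each onset (a coherent whole-body jolt in a random
    direction), on top of a common Gaussian random-walk baseline of
    per-frame step SD ``baseline_motion``.  With zero baseline the measured
    startle magnitude equals the gain exactly.
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=int))
    if np.any(onsets < 1) or np.any(onsets + 5 > n_frames):
        raise ValueError("onsets (plus 5-frame window) must lie within the track")
    rng = np.random.default_rng(seed)
    steps = np.zeros((n_frames, 2))
    if baseline_motion > 0:
        steps[1:] += rng.normal(0.0, baseline_motion, size=(n_frames - 1, 2))
    for f in onsets:
        theta = rng.uniform(0, 2 * np.pi)
        steps[f:f + 5] += startle_gain * np.array([np.cos(theta), np.sin(theta)])
    pos = np.asarray(start_xy) + np.cumsum(steps, axis=0)

    parts = DEFAULT_PARTS
    coords = np.empty((n_frames, len(parts), 2))
    for i, name in enumerate(parts):
        coords[:, i, :] = pos + 10.0 * np.asarray(_PART_OFFSETS[name])  # px offsets
    if dropout > 0:
        mask = rng.random((n_frames, len(parts))) < dropout
        coords[mask] = np.nan
    meta = {"onsets": onsets.tolist(), "startle_gain": startle_gain,
            "baseline_motion": baseline_motion, "seed": seed, "dropout": dropout}
    return PoseTrack(fps=fps, body_parts=parts, coords=coords, units="px", meta=meta)


# -- synthetic ABR epochs -----------------------------------------------------

def abr_template(fs: float = 16_000.0, epoch_ms: float = 12.0) -> np.ndarray:
    """A stylized ABR waveform: five alternating waves, Wave 1 positive.

    Gaussian-windowed peaks at 3.0..6.2 ms with decaying amplitude, peak
    amplitude 1 (arbitrary voltage units).  Wave latencies are placed
    beyond the span of the causal cross-talk filter (click onset plus the
    default 32 taps, i.e. ~2.25 ms at 16 kHz): electrical cross-talk is
    near-instantaneous while the neural response is delayed, and keeping
    the two disjoint in lag is what makes them separable — in the
    generator as in a physical recording.
    """
    n = int(round(epoch_ms / 1000.0 * fs))
    t_ms = np.arange(n) / fs * 1000.0
    w = np.zeros(n)
    for i, peak_ms in enumerate((3.0, 3.8, 4.6, 5.4, 6.2)):
        amp = (-1.0) ** i * 0.9 ** i
        w += amp * np.exp(-0.5 * ((t_ms - peak_ms) / 0.18) ** 2)
    return w / np.max(np.abs(w))


@dataclass
class SynthABRSet:
    fs: float
    neural: np.ndarray        # (n_epochs, samples)
    speaker: np.ndarray       # (n_epochs, samples)
    true_template: np.ndarray
    attenuation_db: float
    leak_gain: float
    leak_delay: int           # samples
    noise_sd: float
    side: str
    artifact_idx: np.ndarray
    meta: dict = field(default_factory=dict)


def synth_abr(n_epochs: int = 750, *, fs: float = 16_000.0, epoch_ms: float = 12.0,
              attenuation_db: float = 0.0, leak_gain: float = 0.3,
              leak_delay: int = 3, noise_sd: float = 0.1, side: str = "right",
              artifact_frac: float = 0.0, artifact_scale: float = 10.0,
              seed=None) -> SynthABRSet:
    """Epoched two-channel ABR data with known generative structure.

    neural = 10^(-attenuation/20) * template (sign-flipped for left-side
    stimulation) + leak_gain * speaker delayed by leak_delay samples +
    white noise.  A fraction of epochs optionally carries an injected
    high-frequency artifact transient of ``artifact_scale`` times the clean
    peak-to-peak, for outlier-rejection tests.
    """
    if n_epochs < 20:
        raise ValueError("need at least 20 epochs")
    rng = np.random.default_rng(seed)
    template = abr_template(fs, epoch_ms)
    n_samp = len(template)

    click = np.zeros(n_samp)
    click_start = int(round(0.25e-3 * fs))
    click[click_start:click_start + max(1, int(round(0.1e-3 * fs)))] = 1.0
    speaker = np.tile(click, (n_epochs, 1))

    amp = 10.0 ** (-attenuation_db / 20.0)
    sign = -1.0 if side == "left" else 1.0
    leak = leak_gain * np.roll(click, leak_delay)
    leak[:leak_delay] = 0.0
    neural = (sign * amp * template + leak
              + rng.normal(0.0, noise_sd, size=(n_epochs, n_samp)))

    n_art = int(round(artifact_frac * n_epochs))
    artifact_idx = np.sort(rng.choice(n_epochs, size=n_art, replace=False)) \
        if n_art else np.array([], dtype=int)
    if n_art:
        clean_ptp = np.ptp(sign * amp * template + leak)
        base = max(clean_ptp, 6.0 * noise_sd)
        t = np.arange(n_samp) / fs
        # 1 kHz burst transient: survives the 100 Hz high-pass intact
        burst = np.sin(2 * np.pi * 1000.0 * t) * np.exp(-((t - 0.004) / 0.001) ** 2)
        for i in artifact_idx:
            neural[i] += artifact_scale * base * burst

    meta = {"n_epochs": n_epochs, "epoch_ms": epoch_ms, "seed": seed,
            "artifact_frac": artifact_frac, "artifact_scale": artifact_scale}
    return SynthABRSet(fs=fs, neural=neural, speaker=speaker,
                       true_template=template, attenuation_db=attenuation_db,
                       leak_gain=leak_gain, leak_delay=leak_delay,
                       noise_sd=noise_sd, side=side, artifact_idx=artifact_idx,
                       meta=meta)
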