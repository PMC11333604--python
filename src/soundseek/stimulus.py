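"""Goal-speaker sound stream: gamma-interval burst trains and waveforms.

The stimulus is an ongoing stream of 10 ms narrowband noise bursts whose
onset-to-onset intervals are i.i.d. draws from a gamma distribution.  The
gamma is parameterized by moment matching so that the repetition rate
(bursts/s) and the irregularity (SD of the inter-burst interval, ms) are
independently controllable:

    mean interval mu = 1000 / rep_rate   (ms)
    shape = mu**2 / sigma**2,  scale = sigma**2 / mu

In the fixed-parameter task every trial uses 4 Hz, 31.6 ms irregularity,
70 dB SPL, 10 kHz center frequency; in the variable-parameter task each
trial draws log-uniformly from the ranges below.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: Sampling ranges for the variable-parameter task (log-uniform per trial).
VARIABLE_RANGES = {
    "center_freq_khz": (5.0, 15.0),
    "level_db": (65.0, 90.0),
    "rep_rate_hz": (3.0, 10.0),
    "irregularity_ms": (1.0, 100.0),
}

TRITONE = np.sqrt(2.0)  # frequency ratio of the tritone interval


@dataclass(frozen=True)
class StimulusParams:
    rep_rate_hz: float = 4.0
    irregularity_ms: float = 31.6
    center_freq_khz: float = 10.0
    level_db: float = 70.0
    bandwidth_khz: float = 3.0
    burst_dur_ms: float = 10.0


@dataclass(frozen=True)
class BurstTrain:
    onset_times: np.ndarray  # strictly increasing, s
    params: StimulusParams
    duration: float          # s


def fixed_params() -> StimulusParams:
    """The fixed-task stimulus (same on every trial)."""
    return StimulusParams()


def gamma_shape_scale(rep_rate_hz: float, irregularity_ms: float) -> tuple[float, float]:
    """Moment-matched gamma (shape, scale in ms) for a given rate and SD."""
    if rep_rate_hz <= 0 or irregularity_ms <= 0:
        raise ValueError("rep_rate and irregularity must be positive")
    mu = 1000.0 / rep_rate_hz
    shape = (mu / irregularity_ms) ** 2
    scale = irregularity_ms**2 / mu
    return shape, scale


def sample_burst_train(params: StimulusParams, duration_s: float,
                       seed=None, rng=None) -> BurstTrain:
    """Draw burst onsets by summing i.i.d. gamma intervals from t = 0.

    Intervals shorter than the burst duration are redrawn so that bursts
    never overlap (a physical speaker cannot), which only matters at
    extreme irregularity.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed) if rng is None else rng
    shape, scale_ms = gamma_shape_scale(params.rep_rate_hz, params.irregularity_ms)
    scale_s = scale_ms / 1000.0
    min_iv = params.burst_dur_ms / 1000.0

    onsets = []
    t = 0.0
    # draw in chunks for speed; resample sub-burst-length intervals
    expected_n = int(duration_s * params.rep_rate_hz * 1.5) + 16
    while t <= duration_s:
        ivs = rng.gamma(shape, scale_s, size=expected_n)
        for iv in ivs:
            while iv < min_iv:
                iv = rng.gamma(shape, scale_s)
            t += iv
            if t > duration_s:
                break
            onsets.append(t)
        # loop again if the chunk ran out before the duration was covered
    return BurstTrain(onset_times=np.asarray(onsets), params=params,
                      duration=float(duration_s))


def sample_variable_params(rng, mode: str = "log") -> StimulusParams:
    """Per-trial stimulus draw for the variable-parameter task.

    Parameters are drawn independently from their ranges, log-uniformly by
    default (the ranges span up to two decades); ``mode='linear'`` gives
    plain uniform draws.
    """
    draws = {}
    for name, (lo, hi) in VARIABLE_RANGES.items():
        if mode == "log":
            draws[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        elif mode == "linear":
            draws[name] = float(rng.uniform(lo, hi))
        else:
            raise ValueError(f"unknown sampling mode {mode!r}")
    return replace(StimulusParams(), **draws)


def synth_burst_waveform(params: StimulusParams, fs: float, seed=None, rng=None) -> np.ndarray:
    """One band-limited noise burst (10 ms default) at the given sample rate.

    White noise is band-passed by zeroing FFT bins outside
    [f0 - bw/2, f0 + bw/2], then peak-normalized.
    """
    f_hi = (params.center_freq_khz + params.bandwidth_khz / 2.0) * 1000.0
    f_lo = (params.center_freq_khz - params.bandwidth_khz / 2.0) * 1000.0
    if fs <= 2.0 * f_hi:
        raise ValueError(f"fs={fs} too low for content up to {f_hi} Hz")
    rng = np.random.default_rng(seed) if rng is None else rng
    n = int(round(params.burst_dur_ms / 1000.0 * fs))
    noise = rng.standard_normal(n)
    spec = np.fft.rfft(noise)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < f_lo) | (freqs > f_hi)] = 0.0
    burst = np.fft.irfft(spec, n=n)
    peak = np.max(np.abs(burst))
    return burst / peak if peak > 0 else burst


def error_tritone(fs: float, base_freq_hz: float = 8000.0,
                  duration_s: float = 0.25) -> np.ndarray:
    """The error sound: a tritone (base frequency plus base * sqrt(2))."""
    if fs <= 2.0 * base_freq_hz * TRITONE:
        raise ValueError("fs too low for the tritone's upper component")
    t = np.arange(int(round(duration_s * fs))) / fs
    return 0.5 * (np.sin(2 * np.pi * base_freq_hz * t)
                  + np.sin(2 * np.pi * base_freq_hz * TRITONE * t))
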