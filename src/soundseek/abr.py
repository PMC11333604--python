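"""Auditory brainstem response (ABR) epoch preprocessing and averaging.

Two-channel recordings (neural voltage + speaker voltage, 16 kHz) of the
response to a 0.1 ms click are processed in four steps:

1. cross-talk removal: the best (least-squares) FIR filter predicting the
   neural channel from the speaker channel is fit across all epochs
   jointly and its prediction subtracted;
2. zero-phase high-pass filtering above 100 Hz (4th-order Butterworth,
   forward-backward) to remove DC and drift;
3. outlier rejection: epochs in the top 5% of voltage excursion
   (peak-to-peak) or of standard deviation are removed (union of the two
   criteria, read literally from "excursion or standard deviation");
4. averaging ~750 repetitions, with responses to left-side sounds inverted
   so Wave 1 is expected positive in all cases.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

DEFAULT_FS = 16_000.0
HIGHPASS_HZ = 100.0
REJECT_PCT = 5.0
CROSSTALK_TAPS = 32


@dataclass
class ABRRecording:
    fs: float
    epochs: np.ndarray      # (n, samples) neural voltage
    speaker: np.ndarray     # (n, samples) speaker voltage
    side: str = "right"     # 'left' | 'right'
    level_dba: float = 70.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.epochs = np.atleast_2d(np.asarray(self.epochs, dtype=float))
        self.speaker = np.atleast_2d(np.asarray(self.speaker, dtype=float))
        if self.epochs.shape != self.speaker.shape:
            raise ValueError("neural and speaker epoch arrays must match in shape")
        if self.fs <= 0:
            raise ValueError("fs must be positive")


def _lagged_design(x: np.ndarray, n_taps: int) -> np.ndarray:
    """Causal lag matrix per epoch: column j is x delayed by j samples."""
    n, s = x.shape
    X = np.zeros((n, s, n_taps))
    for j in range(n_taps):
        X[:, j:, j] = x[:, :s - j] if j else x
    return X.reshape(n * s, n_taps)


def remove_crosstalk(neural: np.ndarray, speaker: np.ndarray,
                     n_taps: int = CROSSTALK_TAPS) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the least-squares FIR prediction of neural from speaker.

    Returns (residual epochs, fitted filter taps).  A silent speaker
    channel (rank-deficient fit) yields a zero filter with a warning.
    """
    if n_taps < 1:
        raise ValueError("n_taps must be >= 1")
    neural = np.atleast_2d(np.asarray(neural, dtype=float))
    speaker = np.atleast_2d(np.asarray(speaker, dtype=float))
    if np.max(np.abs(speaker)) == 0:
        warnings.warn("speaker channel is silent; cross-talk filter set to zero")
        return neural.copy(), np.zeros(n_taps)
    X = _lagged_design(speaker, n_taps)
    y = neural.ravel()
    taps, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < n_taps:
        warnings.warn("rank-deficient cross-talk design; filter may be non-unique")
    pred = signal.lfilter(taps, [1.0], speaker, axis=1)
    return neural - pred, taps


def highpass(epochs: np.ndarray, cutoff_hz: float = HIGHPASS_HZ,
             fs: float = DEFAULT_FS) -> np.ndarray:
    """Zero-phase 4th-order Butterworth high-pass along the sample axis."""
    if not 0 < cutoff_hz < fs / 2:
        raise ValueError("cutoff must be in (0, fs/2)")
    sos = signal.butter(4, cutoff_hz, btype="highpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(epochs, dtype=float), axis=-1)


def reject_outliers(epochs: np.ndarray, pct: float = REJECT_PCT) -> tuple[np.ndarray, dict]:
    """Drop epochs in the top ``pct`` percent of excursion or of SD.

    Excursion is peak-to-peak voltage per epoch.  The rejected set is the
    union of the two rank-based criteria, so the kept fraction lies in
    [1 - 2 pct/100, 1 - pct/100].  Ties break by epoch order (stable).
    Fewer than 20 epochs: all kept, with a warning.
    """
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    n = len(epochs)
    report = {"n_epochs": n, "pct": pct}
    if n < 20:
        warnings.warn("fewer than 20 epochs; outlier rejection skipped")
        report.update(rejected=np.array([], dtype=int), n_rejected=0, kept_fraction=1.0)
        return epochs.copy(), report
    k = math.ceil(n * pct / 100.0)
    excursion = np.ptp(epochs, axis=1)
    sd = np.std(epochs, axis=1)
    top_exc = np.argsort(-excursion, kind="stable")[:k]
    top_sd = np.argsort(-sd, kind="stable")[:k]
    rejected = np.union1d(top_exc, top_sd)
    keep = np.setdiff1d(np.arange(n), rejected)
    report.update(rejected=rejected, n_rejected=len(rejected),
                  rejected_excursion=np.sort(top_exc),
                  rejected_sd=np.sort(top_sd),
                  kept_fraction=len(keep) / n)
    return epochs[keep], report


def average_and_orient(epochs: np.ndarray, side: str = "right") -> np.ndarray:
    """Pointwise mean over epochs, inverted for left-side stimulation.

    The non-inverting electrode sits at the left ear, so Wave 1 is negative
    for left-side sounds; inversion makes it positive in all cases.
    """
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    if len(epochs) == 0:
        raise ValueError("need at least one epoch")
    avg = epochs.mean(axis=0)
    return -avg if side == "left" else avg


def template_amplitude(avg: np.ndarray, template: np.ndarray) -> float:
    """Matched-filter amplitude: least-squares scale of template in avg."""
    template = np.asarray(template, dtype=float)
    denom = float(template @ template)
    if denom == 0:
        raise ValueError("template is identically zero")
    return float(avg @ template) / denom


def process_recording(rec: ABRRecording, *, n_taps: int = CROSSTALK_TAPS,
                      cutoff_hz: float = HIGHPASS_HZ,
                      pct: float = REJECT_PCT) -> dict:
    """Full pipeline: cross-talk removal, high-pass, rejection, average.

    Returns the averaged, oriented waveform plus a QC report (fitted
    filter taps, rejection counts).
    """
    cleaned, taps = remove_crosstalk(rec.epochs, rec.speaker, n_taps=n_taps)
    filtered = highpass(cleaned, cutoff_hz=cutoff_hz, fs=rec.fs)
    kept, report = reject_outliers(filtered, pct=pct)
    avg = average_and_orient(kept, side=rec.side)
    return {"average": avg, "crosstalk_taps": taps, "rejection": report,
            "n_averaged": len(kept), "fs": rec.fs, "side": rec.side,
            "level_dba": rec.level_dba}
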