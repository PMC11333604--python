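"""ABR preprocessing: cross-talk removal, filtering, rejection, averaging."""

import numpy as np
import pytest

from soundseek.abr import (ABRRecording, average_and_orient, highpass,
                           process_recording, reject_outliers, remove_crosstalk,
                           template_amplitude)
from soundseek.synth import abr_template, synth_abr

FS = 16_000.0


def test_crosstalk_zero_leak_preserves_signal():
    s = synth_abr(100, leak_gain=0.0, noise_sd=0.05, seed=1)
    resid, taps = remove_crosstalk(s.neural, s.speaker)
    # the neural signal (waves at >2.5 ms) is out of reach of the causal
    # click-lag filter, so the residual matches the input
    assert np.corrcoef(resid.ravel(), s.neural.ravel())[0, 1] > 0.999


def test_crosstalk_pure_leak_removed():
    s = synth_abr(100, attenuation_db=300.0, leak_gain=0.3, leak_delay=3,
                  noise_sd=0.0, seed=2)
    resid, taps = remove_crosstalk(s.neural, s.speaker, n_taps=8)
    assert np.sum(resid**2) < 0.01 * np.sum(s.neural**2)
    assert taps[3] == pytest.approx(0.3, abs=1e-6)


def test_crosstalk_template_plus_leak():
    s = synth_abr(400, leak_gain=0.5, noise_sd=0.02, seed=3)
    resid, _ = remove_crosstalk(s.neural, s.speaker)
    avg = resid.mean(axis=0)
    assert np.corrcoef(avg, s.true_template)[0, 1] > 0.99


def test_crosstalk_silent_speaker_warns_zero_filter():
    neural = np.random.default_rng(0).normal(size=(30, 100))
    with pytest.warns(UserWarning):
        resid, taps = remove_crosstalk(neural, np.zeros_like(neural))
    assert np.array_equal(resid, neural)
    assert np.allclose(taps, 0.0)
    with pytest.raises(ValueError):
        remove_crosstalk(neural, np.zeros_like(neural), n_taps=0)


def test_highpass_removes_dc_and_drift():
    const = np.full((3, 2000), 4.2)
    out = highpass(const, fs=FS)
    assert np.max(np.abs(out)) < 1e-6


def test_highpass_frequency_response():
    t = np.arange(int(FS)) / FS  # 1 s
    low = np.sin(2 * np.pi * 10.0 * t)
    hi = np.sin(2 * np.pi * 1000.0 * t)
    out_low = highpass(low[None, :], fs=FS)[0]
    out_hi = highpass(hi[None, :], fs=FS)[0]
    mid = slice(2000, -2000)  # ignore filter edges
    atten_low = 20 * np.log10(np.std(out_low[mid]) / np.std(low[mid]))
    atten_hi = 20 * np.log10(np.std(out_hi[mid]) / np.std(hi[mid]))
    assert atten_low <= -40.0
    assert abs(atten_hi) <= 1.0
    # idempotent for in-band content
    twice = highpass(out_hi[None, :], fs=FS)[0]
    assert np.allclose(twice[mid], out_hi[mid], atol=0.02)


def test_highpass_invalid_cutoff():
    with pytest.raises(ValueError):
        highpass(np.zeros((2, 100)), cutoff_hz=9000.0, fs=FS)


def test_reject_identical_epochs_keeps_950():
    epochs = np.tile(np.sin(np.linspace(0, 6, 80)), (1000, 1))
    kept, report = reject_outliers(epochs)
    assert len(kept) == 950
    assert report["kept_fraction"] == pytest.approx(0.95)
    # stable tie-break: the rejected 50 are the first 50 epochs
    assert np.array_equal(report["rejected"], np.arange(50))


def test_reject_injected_artifacts():
    s = synth_abr(500, noise_sd=0.1, artifact_frac=0.05, artifact_scale=10.0,
                  seed=5)
    kept, report = reject_outliers(s.neural)
    assert set(s.artifact_idx.tolist()) <= set(report["rejected"].tolist())
    assert 0.90 <= report["kept_fraction"] <= 0.95


def test_reject_union_bounds():
    rng = np.random.default_rng(7)
    n, s = 100, 200
    base = rng.normal(0, 0.1, size=(n, s))
    # correlated criteria: 5 epochs extreme in both ptp and sd
    corr = base.copy()
    corr[:5] *= 30.0
    _, rep = reject_outliers(corr)
    assert rep["n_rejected"] == 5
    # disjoint criteria: spikes (high ptp) vs sustained sines (high sd)
    disj = base.copy()
    disj[:5, 100] += 50.0                      # single-sample spikes: top ptp
    disj[5:10] += 6.0 * np.sin(np.linspace(0, 20, s))  # sustained: top sd
    _, rep = reject_outliers(disj)
    assert rep["n_rejected"] == 10


def test_reject_too_few_epochs_warns():
    with pytest.warns(UserWarning):
        kept, rep = reject_outliers(np.zeros((10, 50)))
    assert len(kept) == 10 and rep["kept_fraction"] == 1.0


def test_average_orientation():
    w = abr_template()
    left = np.tile(-w, (20, 1))
    assert np.allclose(average_and_orient(left, side="left"), w)
    right = np.tile(w, (20, 1))
    assert np.allclose(average_and_orient(right, side="right"), w)
    with pytest.raises(ValueError):
        average_and_orient(np.empty((0, 10)))


def test_averaging_noise_shrinks_like_sqrt_n():
    rng = np.random.default_rng(9)
    epochs = rng.normal(0, 1.0, size=(750, 400))
    avg = epochs.mean(axis=0)
    ratio = np.std(epochs[0]) / np.std(avg)
    assert ratio == pytest.approx(np.sqrt(750), rel=0.15)


def test_pipeline_recovers_template_at_default_snr():
    s = synth_abr(750, noise_sd=0.1, leak_gain=0.3, artifact_frac=0.05, seed=10)
    res = process_recording(ABRRecording(fs=s.fs, epochs=s.neural,
                                         speaker=s.speaker, side=s.side))
    target = highpass(s.true_template[None, :], fs=s.fs)[0]
    assert np.corrcoef(res["average"], target)[0, 1] > 0.95
    assert res["n_averaged"] >= 0.90 * 750


def test_pipeline_left_side_orientation():
    s = synth_abr(200, side="left", noise_sd=0.05, seed=11)
    res = process_recording(ABRRecording(fs=s.fs, epochs=s.neural,
                                         speaker=s.speaker, side="left"))
    target = highpass(s.true_template[None, :], fs=s.fs)[0]
    assert template_amplitude(res["average"], target) > 0.9  # re-inverted


def test_template_amplitude_guard():
    with pytest.raises(ValueError):
        template_amplitude(np.ones(10), np.zeros(10))
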