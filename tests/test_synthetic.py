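"""Signal generator: background spectrum, oscillation power, spike
transients, and session assembly."""

import numpy as np
import pytest

from thetaloop import (
    LearnerModel,
    NoiseModel,
    OscillationSpec,
    SignalEpoch,
    SpikeModel,
    add_oscillation,
    generate_background,
    generate_experiment,
    generate_session,
    generate_trial_epoch,
    inject_spikes,
    oscillation_waveform,
    simulate_responses,
    welch_psd,
)
from thetaloop.config import WelchSettings
from thetaloop.synthetic import spike_waveform

FS = 512.0


# --------------------------------------------------------------- background

def test_background_rms_matches_scale_exactly():
    epoch = generate_background(30.0, FS, NoiseModel(exponent=2.0, scale=30.0), seed=1)
    rms = np.sqrt(np.mean(epoch.samples**2, axis=1))
    assert np.allclose(rms, 30.0, rtol=1e-9)


def test_background_loglog_psd_slope():
    for exponent in (1.0, 2.0):
        epoch = generate_background(120.0, FS, NoiseModel(exponent=exponent, scale=30.0), seed=2)
        est = welch_psd(epoch, WelchSettings(window_s=4.0, overlap=0.5))
        mask = (est.freqs >= 1.0) & (est.freqs <= 100.0)
        logf = np.log10(est.freqs[mask])
        logp = np.log10(est.channel_mean()[mask])
        slope = np.polyfit(logf, logp, 1)[0]
        assert abs(slope + exponent) < 0.1


def test_background_channels_independent_above_low_frequencies():
    # 1/f^2 noise is dominated by a few low-frequency degrees of freedom, so
    # raw sample correlations between independent channels have huge variance;
    # independence is assessed on the > 2 Hz content where many dof average out
    from scipy import signal as sps

    epoch = generate_background(60.0, FS, NoiseModel(), seed=3)
    sos = sps.butter(4, 2.0, btype="highpass", fs=FS, output="sos")
    hp = sps.sosfiltfilt(sos, epoch.samples, axis=1)
    c = np.corrcoef(hp)
    off_diag = c[~np.eye(4, dtype=bool)]
    assert np.max(np.abs(off_diag)) < 0.1


def test_background_zero_scale_and_determinism():
    silent = generate_background(2.0, FS, NoiseModel(scale=0.0), seed=0)
    assert np.all(silent.samples == 0)
    a = generate_background(2.0, FS, NoiseModel(), seed=7)
    b = generate_background(2.0, FS, NoiseModel(), seed=7)
    assert np.array_equal(a.samples, b.samples)
    with pytest.raises(ValueError):
        generate_background(0.0, FS, NoiseModel(), seed=0)
    with pytest.raises(ValueError):
        generate_background(1.0, -1.0, NoiseModel(), seed=0)


# -------------------------------------------------------------- oscillation

def test_sinusoid_mean_square_is_half_amplitude_squared():
    # 13 s at 6 Hz is an integer number of cycles, so the identity is exact
    wave = oscillation_waveform(int(13 * FS), FS, OscillationSpec(6.0, 0.0, 10.0), seed=4)
    assert np.mean(wave**2) == pytest.approx(50.0, rel=1e-6)
    assert np.max(np.abs(wave)) == pytest.approx(10.0, rel=1e-3)


def test_bandlimited_oscillation_rms_and_band_confinement():
    spec = OscillationSpec(6.0, 4.0, 20.0)
    wave = oscillation_waveform(int(60 * FS), FS, spec, seed=5)
    assert np.mean(wave**2) == pytest.approx(200.0, rel=1e-9)
    epoch = SignalEpoch(wave[None, :], FS, ("MTL1",))
    est = welch_psd(epoch, WelchSettings(window_s=2.0))
    in_band = (est.freqs >= 3.0) & (est.freqs <= 9.0)
    power_in = np.trapezoid(est.channel_mean()[in_band], est.freqs[in_band])
    power_total = np.trapezoid(est.channel_mean(), est.freqs)
    assert power_in / power_total > 0.95


def test_oscillation_band_must_fit_nyquist_and_zero_amplitude():
    with pytest.raises(ValueError):
        oscillation_waveform(512, FS, OscillationSpec(250.0, 20.0, 1.0), seed=0)
    assert np.all(oscillation_waveform(512, FS, OscillationSpec(6.0, 2.0, 0.0), seed=0) == 0)


def test_add_oscillation_is_additive_and_preserves_input():
    base = generate_background(5.0, FS, NoiseModel(), seed=6)
    before = base.samples.copy()
    spec = OscillationSpec(6.0, 0.0, 15.0)
    out = add_oscillation(base, spec, seed=9)
    assert np.array_equal(base.samples, before)
    diff = out.samples - base.samples
    # same waveform added on every channel
    assert np.allclose(diff, diff[0][None, :])
    assert np.mean(diff[0] ** 2) == pytest.approx(15.0**2 / 2, rel=1e-2)


# ------------------------------------------------------------------- spikes

def test_spike_waveform_peak_equals_amplitude():
    model = SpikeModel(amplitude=300.0)
    w = spike_waveform(model, FS)
    assert np.max(np.abs(w)) == pytest.approx(300.0)


def test_injected_spikes_detectable_at_reported_onsets():
    quiet = SignalEpoch(np.zeros((4, int(30 * FS))), FS, ("MTL1", "MTL2", "MTL3", "MTL4"))
    model = SpikeModel(rate=0.3, amplitude=300.0)
    noisy, onsets = inject_spikes(quiet, model, seed=12)
    assert len(onsets) > 0
    assert np.all(np.diff(onsets) >= 0)
    # oracle: every reported onset has a large deflection nearby on channel 0
    for onset in onsets:
        i = int(round(onset * FS))
        lo, hi = max(0, i - 60), min(noisy.n_samples, i + 60)
        assert np.max(np.abs(noisy.samples[0, lo:hi])) > 150.0
    # channel amplitude profile respected where a single spike is isolated
    iso = [o for o in onsets if np.min(np.abs(np.delete(onsets, np.where(onsets == o)) - o)) > 0.5] if len(onsets) > 1 else list(onsets)
    if iso:
        i = int(round(iso[0] * FS))
        lo, hi = max(0, i - 60), min(noisy.n_samples, i + 60)
        peaks = np.max(np.abs(noisy.samples[:, lo:hi]), axis=1)
        assert np.allclose(peaks / peaks[0], (1.0, 0.8, 0.6, 0.4), rtol=1e-6)


def test_zero_rate_or_amplitude_leaves_signal_untouched():
    base = generate_background(5.0, FS, NoiseModel(), seed=1)
    out, onsets = inject_spikes(base, SpikeModel(rate=0.0), seed=0)
    assert len(onsets) == 0
    assert np.array_equal(out.samples, base.samples)


# ----------------------------------------------------------------- sessions

def test_session_theta_amplified_in_encoding_windows(plans4_small):
    plan = plans4_small[0]
    learner = LearnerModel(theta_gain_by_session=(4.0,), jitter_sigma=0.0)
    rec = generate_session(plan, learner, NoiseModel(), OscillationSpec(), None, seed=21)
    assert rec.epoch.duration == pytest.approx(plan.duration_s)
    tl = plan.timeline

    def theta_power(seg):
        est = welch_psd(seg)
        mask = (est.freqs >= 4) & (est.freqs <= 8)
        return np.trapezoid(est.channel_mean()[mask], est.freqs[mask])

    enc = rec.epoch.segment(plan.trial_onset(0), plan.trial_onset(0) + tl.encoding_s)
    rest = rec.epoch.segment(0.0, tl.rest_s)
    assert theta_power(enc) > 2.0 * theta_power(rest)


def test_session_ground_truth_shapes_and_determinism(plans4_small):
    plan = plans4_small[0]
    learner = LearnerModel(theta_gain_by_session=(1.0,))
    a = generate_session(plan, learner, NoiseModel(), OscillationSpec(), SpikeModel(), seed=8)
    b = generate_session(plan, learner, NoiseModel(), OscillationSpec(), SpikeModel(), seed=8)
    assert np.array_equal(a.epoch.samples, b.epoch.samples)
    assert a.responses == b.responses
    gt = a.ground_truth
    assert gt.n_trials == plan.n_trials
    assert len(gt.spike_onsets_by_trial) == plan.n_trials
    assert np.all(gt.theta_factor > 0)


def test_session_index_must_lie_in_learner_trajectory(plans4_small):
    learner = LearnerModel(theta_gain_by_session=(1.0, 1.0))
    with pytest.raises(ValueError):
        generate_session(plans4_small[0], learner, NoiseModel(), OscillationSpec(), None, seed=0, session_index=2)


def test_experiment_plan_count_must_match_gains(plans4_small):
    learner = LearnerModel(theta_gain_by_session=(1.0, 1.0))
    with pytest.raises(ValueError):
        generate_experiment(plans4_small, learner, NoiseModel(), OscillationSpec(), None, seed=0)


def test_trial_epoch_theta_scales_with_factor():
    noise = NoiseModel(scale=5.0)
    osc = OscillationSpec(6.0, 4.0, 20.0)
    lo, _ = generate_trial_epoch(1.0, noise, osc, None, seed=31)
    hi, _ = generate_trial_epoch(3.0, noise, osc, None, seed=31)

    def theta_power(epoch):
        est = welch_psd(epoch)
        mask = (est.freqs >= 4) & (est.freqs <= 8)
        return np.trapezoid(est.channel_mean()[mask], est.freqs[mask])

    ratio = theta_power(hi) / theta_power(lo)
    assert 5.0 < ratio < 12.0  # amplitude x3 -> power x9, background dilutes


def test_simulated_responses_follow_scheduled_success(plans4_small):
    plan = plans4_small[0]
    learner = LearnerModel(theta_gain_by_session=(1.0,))
    rec = generate_session(plan, learner, NoiseModel(), OscillationSpec(), None, seed=40)
    gt = rec.ground_truth
    for i, (trial, (a1, a2)) in enumerate(zip(plan.trials, rec.responses)):
        truth = "old" if trial.probe_is_old else "new"
        assert (a1 == truth) == bool(gt.success[i])
        if trial.probe_is_old and a1 == "old":
            assert (a2 == trial.correct_position) == bool(gt.task2_success[i])
        else:
            assert a2 is None
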