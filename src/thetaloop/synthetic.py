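"""Synthetic intracranial EEG with known ground truth.

Emulates a 4-contact mesial-temporal recording: 1/f^beta background, a
narrowband theta (4–8 Hz) oscillation whose amplitude during each encoding
period is controlled per trial, and epileptic spike transients synchronous
across contacts. A "learner" model imposes a session-wise trajectory on theta
gain and couples per-trial theta power to recognition success, so that the
offline statistics battery can be validated against known parameters.

Everything is deterministic given a seed; components are additive, so
background, oscillation and spikes can be generated and checked independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps
from scipy.special import expit, logit

from .config import DEFAULT_CHANNELS, Timeline
from .paradigm import SessionPlan

__all__ = [
    "SignalEpoch",
    "NoiseModel",
    "OscillationSpec",
    "SpikeModel",
    "LearnerModel",
    "GroundTruth",
    "SessionRecording",
    "generate_background",
    "oscillation_waveform",
    "add_oscillation",
    "spike_waveform",
    "inject_spikes",
    "generate_trial_epoch",
    "generate_session",
    "generate_experiment",
    "simulate_responses",
]


# ----------------------------------------------------------------- containers

@dataclass
class SignalEpoch:
    """A block of multichannel samples in µV at a fixed sampling rate."""

    samples: np.ndarray  # [n_channels, n_samples]
    fs: float
    channel_labels: tuple[str, ...]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError("channel_labels length must match sample rows")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "SignalEpoch":
        return SignalEpoch(self.samples.copy(), self.fs, self.channel_labels, self.start_time)

    def segment(self, t0: float, t1: float) -> "SignalEpoch":
        """Samples in [t0, t1) measured from this epoch's start_time."""
        i0 = int(round((t0 - self.start_time) * self.fs))
        i1 = int(round((t1 - self.start_time) * self.fs))
        if i0 < 0 or i1 > self.n_samples or i1 <= i0:
            raise ValueError(
                f"segment [{t0}, {t1}) s outside recording "
                f"[{self.start_time}, {self.start_time + self.duration}) s"
            )
        return SignalEpoch(self.samples[:, i0:i1].copy(), self.fs, self.channel_labels, t0)


@dataclass(frozen=True)
class NoiseModel:
    """1/f^beta background: PSD slope ``exponent`` (power scale), RMS ``scale`` µV."""

    exponent: float = 2.0
    scale: float = 30.0

    def __post_init__(self) -> None:
        if self.exponent < 0:
            raise ValueError("exponent must be >= 0")
        if self.scale < 0:
            raise ValueError("scale must be >= 0")


@dataclass(frozen=True)
class OscillationSpec:
    """Narrowband oscillation: bandwidth 0 means a pure sinusoid of peak
    amplitude ``amplitude``; bandwidth > 0 means band-limited noise with the
    same total power (amplitude^2 / 2)."""

    center_freq: float = 6.0
    bandwidth: float = 4.0  # default spans the full 4–8 Hz theta band
    amplitude: float = 20.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.bandwidth < 0:
            raise ValueError("bandwidth must be >= 0")


@dataclass(frozen=True)
class SpikeModel:
    """Epileptic spike transients: Poisson onsets, synchronous across channels
    with a fixed per-channel amplitude profile (focal generator geometry)."""

    rate: float = 0.2
    amplitude: float = 300.0
    width: float = 0.05  # half-duration in s
    waveform: str = "biphasic_sharp"
    channel_profile: tuple[float, ...] = (1.0, 0.8, 0.6, 0.4)

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.waveform not in ("biphasic_sharp", "gaussian_pulse"):
            raise ValueError(f"unknown waveform {self.waveform!r}")


@dataclass(frozen=True)
class LearnerModel:
    """Session-wise theta gain trajectory and behaviour coupling.

    ``behavior_coupling`` is the logit slope on the standardized log theta
    factor: 0 decouples recognition success from theta power entirely.
    """

    theta_gain_by_session: tuple[float, ...] = (1.0,) * 6
    behavior_coupling: float = 0.0
    base_success_prob: float = 0.9
    task2_success_prob: float = 0.7
    jitter_sigma: float = 0.1  # lognormal sigma of per-trial theta factor

    def __post_init__(self) -> None:
        if any(g < 0 for g in self.theta_gain_by_session):
            raise ValueError("session gains must be >= 0")
        if not -1 <= self.behavior_coupling <= 1:
            raise ValueError("behavior_coupling must lie in [-1, 1]")
        if not 0 < self.base_success_prob <= 1:
            raise ValueError("base_success_prob must lie in (0, 1]")

    @property
    def n_sessions(self) -> int:
        return len(self.theta_gain_by_session)


@dataclass
class GroundTruth:
    """Per-trial generator truth for one session."""

    theta_factor: np.ndarray  # true multiplicative theta amplitude factor
    success: np.ndarray  # scheduled task-1 correctness (bool)
    task2_success: np.ndarray  # scheduled task-2 correctness given a task-1 hit
    spike_onsets: np.ndarray  # all spike onset times, s from session start
    spike_onsets_by_trial: list[np.ndarray]  # onsets inside each encoding window

    @property
    def n_trials(self) -> int:
        return len(self.theta_factor)


@dataclass
class SessionRecording:
    """One session: continuous signal plus plan, responses and (for generated
    sessions) the ground truth."""

    epoch: SignalEpoch
    plan: SessionPlan
    responses: list[tuple[Optional[str], Optional[int]]]
    ground_truth: Optional[GroundTruth] = None
    session_index: int = 0


# ----------------------------------------------------------------- components

def generate_background(
    duration: float,
    fs: float,
    noise_model: NoiseModel,
    seed: int,
    n_channels: int = 4,
    channel_labels: Optional[Sequence[str]] = None,
    start_time: float = 0.0,
) -> SignalEpoch:
    """1/f^beta noise by random-phase spectral synthesis, per channel
    independent.

    Spectral amplitudes are deterministic (|S(f)| proportional to
    f^(-beta/2)) and only the phases are random, so the RMS equals
    ``noise_model.scale`` exactly and the long-run spectrum carries no
    realization-level offset; by the central limit theorem the time samples
    are still approximately Gaussian.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    labels = tuple(channel_labels) if channel_labels is not None else DEFAULT_CHANNELS[:n_channels]
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    if noise_model.scale == 0:
        return SignalEpoch(np.zeros((n_channels, n)), fs, labels, start_time)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-noise_model.exponent / 2.0)
    # Parseval: mean square of irfft(S) with |S_k| = shape_k
    weights = np.full(len(shape), 2.0)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[-1] = 1.0
    mean_square = np.sum(weights * shape**2) / n**2
    shape *= noise_model.scale / np.sqrt(mean_square)
    out = np.empty((n_channels, n))
    for ch in range(n_channels):
        phase = rng.uniform(0, 2 * np.pi, size=len(shape))
        spec = shape * np.exp(1j * phase)
        spec[0] = 0.0
        if n % 2 == 0:  # Nyquist coefficient must be real
            spec[-1] = shape[-1] * np.sign(np.cos(phase[-1]))
        out[ch] = np.fft.irfft(spec, n=n)
    return SignalEpoch(out, fs, labels, start_time)


def oscillation_waveform(n_samples: int, fs: float, spec: OscillationSpec, seed: int) -> np.ndarray:
    """Deterministic 1-D oscillation of total power amplitude^2/2.

    Pure sinusoid with random phase when bandwidth is 0; otherwise 4th-order
    band-pass filtered white noise rescaled to RMS amplitude/sqrt(2).
    """
    lo = spec.center_freq - spec.bandwidth / 2.0
    hi = spec.center_freq + spec.bandwidth / 2.0
    if not (0 < lo and hi < fs / 2):
        raise ValueError(
            f"oscillation band [{lo}, {hi}] Hz must lie strictly inside (0, {fs / 2}) Hz"
        )
    if spec.amplitude == 0:
        return np.zeros(n_samples)
    rng = np.random.default_rng(seed)
    if spec.bandwidth == 0:
        phase = rng.uniform(0, 2 * np.pi)
        t = np.arange(n_samples) / fs
        return spec.amplitude * np.sin(2 * np.pi * spec.center_freq * t + phase)
    # pad to stabilize the filter transient, then trim
    pad = int(round(2.0 * fs))
    white = rng.standard_normal(n_samples + 2 * pad)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)[pad : pad + n_samples]
    rms = np.sqrt(np.mean(x**2))
    return x * (spec.amplitude / np.sqrt(2.0) / rms)


def add_oscillation(epoch: SignalEpoch, spec: OscillationSpec, seed: int) -> SignalEpoch:
    """Return epoch + oscillation (same waveform on every channel); the input
    epoch is left unchanged."""
    wave = oscillation_waveform(epoch.n_samples, epoch.fs, spec, seed)
    out = epoch.copy()
    out.samples = out.samples + wave[None, :]
    return out


def spike_waveform(model: SpikeModel, fs: float) -> np.ndarray:
    """Single-spike template, peak absolute value = model.amplitude."""
    sigma = model.width / 2.0
    half = int(round(4 * sigma * fs))
    t = np.arange(-half, half + 1) / fs
    if model.waveform == "gaussian_pulse":
        w = np.exp(-(t**2) / (2 * sigma**2))
    else:  # biphasic_sharp: derivative-of-Gaussian, sharp up-down deflection
        w = -t * np.exp(-(t**2) / (2 * sigma**2))
    return model.amplitude * w / np.max(np.abs(w))


def inject_spikes(
    epoch: SignalEpoch, model: SpikeModel, seed: int
) -> tuple[SignalEpoch, np.ndarray]:
    """Add Poisson-process spike transients; returns (new epoch, onsets in s
    from epoch start_time). Onsets mark the spike template's center."""
    rng = np.random.default_rng(seed)
    n_events = rng.poisson(model.rate * epoch.duration)
    if n_events == 0 or model.amplitude == 0:
        return epoch.copy(), np.array([])
    onsets = np.sort(rng.uniform(0, epoch.duration, size=n_events))
    template = spike_waveform(model, epoch.fs)
    half = len(template) // 2
    profile = np.asarray(model.channel_profile[: epoch.n_channels], dtype=float)
    if len(profile) < epoch.n_channels:
        raise ValueError("channel_profile shorter than channel count")
    out = epoch.copy()
    for onset in onsets:
        c = int(round(onset * epoch.fs))
        a = max(0, c - half)
        b = min(epoch.n_samples, c + half + 1)
        seg = template[a - (c - half) : len(template) - ((c + half + 1) - b)]
        out.samples[:, a:b] += profile[:, None] * seg[None, :]
    return out, onsets + epoch.start_time


# ------------------------------------------------------------------- sessions

def generate_trial_epoch(
    theta_factor: float,
    noise: NoiseModel,
    osc: OscillationSpec,
    spikes: Optional[SpikeModel],
    seed: int,
    duration_s: float = 13.0,
    fs: float = 512.0,
    n_channels: int = 4,
) -> tuple[SignalEpoch, np.ndarray]:
    """One encoding epoch: background + theta at amplitude osc.amplitude *
    theta_factor (+ spikes). Returns (epoch, spike onsets)."""
    ss = np.random.SeedSequence(seed).generate_state(3)
    epoch = generate_background(duration_s, fs, noise, int(ss[0]), n_channels)
    scaled = OscillationSpec(osc.center_freq, osc.bandwidth, osc.amplitude * theta_factor)
    epoch = add_oscillation(epoch, scaled, int(ss[1]))
    if spikes is not None and spikes.rate > 0:
        epoch, onsets = inject_spikes(epoch, spikes, int(ss[2]))
    else:
        onsets = np.array([])
    return epoch, onsets


def _scheduled_success(
    learner: LearnerModel, theta_factors: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Bernoulli recognition outcomes with logit linear in the standardized
    log theta factor times the coupling."""
    gains = np.asarray(learner.theta_gain_by_session, dtype=float)
    safe = gains[gains > 0]
    mu = np.mean(np.log(safe)) if len(safe) else 0.0
    sd = np.sqrt(np.var(np.log(safe)) + learner.jitter_sigma**2) if len(safe) else 0.0
    logf = np.log(np.maximum(theta_factors, 1e-300))
    z = (logf - mu) / sd if sd > 0 else np.zeros_like(logf)
    p = expit(logit(np.clip(learner.base_success_prob, 1e-9, 1 - 1e-9)) + learner.behavior_coupling * z)
    success = rng.uniform(size=len(theta_factors)) < p
    task2 = rng.uniform(size=len(theta_factors)) < learner.task2_success_prob
    return success, task2


def simulate_responses(
    plan: SessionPlan, ground_truth: GroundTruth, seed: int
) -> list[tuple[Optional[str], Optional[int]]]:
    """Turn scheduled correctness indicators into keystroke-level responses."""
    if ground_truth.n_trials != plan.n_trials:
        raise ValueError("ground truth / plan trial count mismatch")
    rng = np.random.default_rng(seed)
    responses: list[tuple[Optional[str], Optional[int]]] = []
    for i, trial in enumerate(plan.trials):
        truth = "old" if trial.probe_is_old else "new"
        wrong = "new" if trial.probe_is_old else "old"
        a1 = truth if ground_truth.success[i] else wrong
        a2: Optional[int] = None
        if trial.probe_is_old and a1 == "old":
            if ground_truth.task2_success[i]:
                a2 = trial.correct_position
            else:
                others = [p for p in range(1, 6) if p != trial.correct_position]
                a2 = int(rng.choice(others))
        responses.append((a1, a2))
    return responses


def generate_session(
    plan: SessionPlan,
    learner: LearnerModel,
    noise: NoiseModel,
    osc: OscillationSpec,
    spikes: Optional[SpikeModel],
    seed: int,
    session_index: int = 0,
) -> SessionRecording:
    """Continuous recording for one session.

    A tonic theta oscillation of amplitude ``osc.amplitude`` runs through the
    whole session (theta is an ongoing rhythm); during trial t's encoding
    window its amplitude is scaled to
    ``osc.amplitude * gain[session_index] * lognormal jitter``. Keeping
    baseline theta outside the encoding periods matters for artifact
    correction: ASR calibrates on the opening rest period, which must contain
    the rhythm it should preserve.
    """
    if not 0 <= session_index < learner.n_sessions:
        raise ValueError(
            f"session_index {session_index} outside learner trajectory "
            f"(n_sessions={learner.n_sessions})"
        )
    tl = plan.timeline
    fs = 512.0
    ss = np.random.SeedSequence([seed, session_index])
    seeds = ss.generate_state(5)
    rng = np.random.default_rng(int(seeds[0]))

    gain = learner.theta_gain_by_session[session_index]
    jitter = np.exp(learner.jitter_sigma * rng.standard_normal(plan.n_trials))
    theta_factor = gain * jitter

    epoch = generate_background(plan.duration_s, fs, noise, int(seeds[1]), len(DEFAULT_CHANNELS))
    n_total = epoch.n_samples
    n_enc = int(round(tl.encoding_s * fs))
    wave = oscillation_waveform(n_total, fs, osc, int(seeds[4]))
    envelope = np.ones(n_total)
    for t in range(plan.n_trials):
        i0 = int(round(plan.trial_onset(t) * fs))
        envelope[i0 : i0 + n_enc] = theta_factor[t]
    epoch.samples += (wave * envelope)[None, :]

    if spikes is not None and spikes.rate > 0:
        epoch, spike_onsets = inject_spikes(epoch, spikes, int(seeds[2]))
    else:
        spike_onsets = np.array([])
    by_trial = []
    for t in range(plan.n_trials):
        t0 = plan.trial_onset(t)
        mask = (spike_onsets >= t0) & (spike_onsets < t0 + tl.encoding_s)
        by_trial.append(spike_onsets[mask])

    success, task2 = _scheduled_success(learner, theta_factor, rng)
    gt = GroundTruth(
        theta_factor=theta_factor,
        success=success,
        task2_success=task2,
        spike_onsets=spike_onsets,
        spike_onsets_by_trial=by_trial,
    )
    responses = simulate_responses(plan, gt, int(seeds[3]))
    return SessionRecording(
        epoch=epoch, plan=plan, responses=responses, ground_truth=gt,
        session_index=session_index,
    )


def generate_experiment(
    plans: Sequence[SessionPlan],
    learner: LearnerModel,
    noise: NoiseModel,
    osc: OscillationSpec,
    spikes: Optional[SpikeModel],
    seed: int,
) -> list[SessionRecording]:
    """One recording per session plan; plan count must match the learner's
    gain trajectory."""
    if len(plans) != learner.n_sessions:
        raise ValueError(
            f"{len(plans)} session plans but learner has {learner.n_sessions} gains"
        )
    return [
        generate_session(plan, learner, noise, osc, spikes, seed, session_index=s)
        for s, plan in enumerate(plans)
    ]
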