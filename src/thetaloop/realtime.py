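"""Closed-loop feedback chain: preprocessing, encoding-epoch extraction,
Welch PSD, theta band power, electrode averaging, and the intermittent bar
feedback protocol.

Per trial: the 13-s encoding epoch is extracted from the continuous
recording; depending on the configuration ASR is skipped (subdural montage)
or applied with fixed k = 4 (depth montage); theta power (4–8 Hz) is
integrated from the Welch PSD of the 12-s analysis window per electrode and
averaged across electrodes; the value is appended to the feedback bar
history shown to the participant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .asr import ASRCalibration, ASRParams, CleaningReport, asr_calibrate, asr_clean
from .config import FilterSpec, RunConfig, WelchSettings
from .paradigm import RecognitionScores, SessionPlan, score_recognition
from .synthetic import SignalEpoch

__all__ = [
    "SpectralEstimate",
    "BandPower",
    "FeedbackState",
    "NFSessionRecord",
    "preprocess",
    "extract_encoding_epoch",
    "welch_psd",
    "band_power",
    "update_feedback",
    "run_closed_loop",
]


@dataclass
class SpectralEstimate:
    """Per-channel Welch PSD in µV²/Hz on a regular frequency grid."""

    freqs: np.ndarray
    psd: np.ndarray  # [n_channels, n_freqs]
    window_s: float
    overlap: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.psd < 0):
            raise ValueError("psd must be non-negative")

    def channel_mean(self) -> np.ndarray:
        return self.psd.mean(axis=0)


@dataclass(frozen=True)
class BandPower:
    per_channel: tuple[float, ...]  # µV²
    mean: float  # µV², arithmetic mean across channels
    log_mean: float  # log10(mean)
    band: tuple[float, float]


@dataclass
class FeedbackState:
    """Append-only history of per-trial feedback values (bar heights are the
    raw µV² values rescaled to the running maximum for display)."""

    history: list[float] = field(default_factory=list)

    @property
    def current_trial(self) -> int:
        return len(self.history)

    def bar_heights(self) -> list[float]:
        if not self.history:
            return []
        peak = max(self.history)
        return [v / peak if peak > 0 else 0.0 for v in self.history]


@dataclass
class NFSessionRecord:
    """Everything one executed session produced."""

    band_powers: list[BandPower]
    feedback: FeedbackState
    scores: RecognitionScores
    k_used: list[Optional[int]]  # None where ASR was skipped
    cleaning_report: CleaningReport
    responses: list
    mode: str
    config_hash: str = ""
    seed: int = 0


def preprocess(raw: SignalEpoch, spec: FilterSpec | None = None) -> SignalEpoch:
    """Zero-phase Butterworth band-pass plus mains notch."""
    spec = spec or FilterSpec()
    spec.validate(raw.fs)
    sos = sps.butter(spec.order, spec.band, btype="bandpass", fs=raw.fs, output="sos")
    b, a = sps.iirnotch(spec.notch, spec.notch_q, fs=raw.fs)
    out = raw.copy()
    out.samples = sps.sosfiltfilt(sos, out.samples, axis=1)
    out.samples = sps.filtfilt(b, a, out.samples, axis=1)
    return out


def extract_encoding_epoch(
    recording: SignalEpoch, trial_onset: float, encoding_s: float = 13.0, lead_s: float = 1.0
) -> tuple[SignalEpoch, SignalEpoch]:
    """(full 13-s epoch, 12-s analysis window dropping the leading blank)."""
    full = recording.segment(trial_onset, trial_onset + encoding_s)
    n_lead = int(round(lead_s * recording.fs))
    analysis = SignalEpoch(
        full.samples[:, n_lead:].copy(), full.fs, full.channel_labels, trial_onset + lead_s
    )
    return full, analysis


def welch_psd(window: SignalEpoch, settings: WelchSettings | None = None) -> SpectralEstimate:
    """Averaged-periodogram PSD: Hann segments of ``window_s`` seconds with
    fractional ``overlap``; 1-s segments give a 1 Hz grid."""
    settings = settings or WelchSettings()
    nperseg = int(round(settings.window_s * window.fs))
    if window.n_samples < nperseg:
        raise ValueError(
            f"window of {window.duration:.3f} s shorter than one "
            f"{settings.window_s}-s Welch segment"
        )
    noverlap = int(round(nperseg * settings.overlap))
    freqs, psd = sps.welch(
        window.samples,
        fs=window.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
        axis=1,
    )
    return SpectralEstimate(freqs=freqs, psd=psd, window_s=settings.window_s, overlap=settings.overlap)


def band_power(psd: SpectralEstimate, lo: float = 4.0, hi: float = 8.0) -> BandPower:
    """Trapezoidal integral of the PSD over [lo, hi] per channel, averaged
    across channels; log_mean is log10 of the mean."""
    if hi <= lo:
        raise ValueError(f"need hi > lo, got [{lo}, {hi}]")
    if lo < psd.freqs[0] or hi > psd.freqs[-1]:
        raise ValueError(f"band [{lo}, {hi}] Hz outside PSD grid")
    mask = (psd.freqs >= lo) & (psd.freqs <= hi)
    per_channel = np.trapezoid(psd.psd[:, mask], psd.freqs[mask], axis=1)
    mean = float(per_channel.mean())
    log_mean = float(np.log10(mean)) if mean > 0 else float("-inf")
    return BandPower(tuple(float(p) for p in per_channel), mean, log_mean, (lo, hi))


def update_feedback(state: FeedbackState, power: BandPower) -> FeedbackState:
    """Append the trial's electrode-averaged theta power to the bar history."""
    state.history.append(power.mean)
    return state


def run_closed_loop(
    plan: SessionPlan,
    recording: SignalEpoch,
    config: RunConfig | None = None,
    responses: Optional[list] = None,
    mode: str = "p01",
) -> NFSessionRecord:
    """Replay (or simulate) one session through the real-time chain.

    ``mode="p01"`` never invokes ASR; ``mode="p02"`` cleans every encoding
    epoch with fixed k = 4, calibrated on the session's opening rest period.
    Deterministic: the same recording and plan give identical records.
    """
    from .config import config_hash

    config = config or RunConfig()
    if mode not in ("p01", "p02"):
        raise ValueError(f"mode must be 'p01' or 'p02', got {mode!r}")
    tl = plan.timeline
    if recording.duration + 1e-9 < plan.duration_s:
        raise ValueError(
            f"recording of {recording.duration:.1f} s does not cover the "
            f"{plan.duration_s:.1f}-s session plan"
        )
    filtered = preprocess(recording, config.filters)

    calib: Optional[ASRCalibration] = None
    cleaning = CleaningReport()
    if mode == "p02":
        rest = filtered.segment(0.0, tl.rest_s)
        calib = asr_calibrate(rest, ASRParams(k=config.asr.k, window_s=config.asr.window_s))

    state = FeedbackState()
    band_powers: list[BandPower] = []
    k_used: list[Optional[int]] = []
    for t in range(plan.n_trials):
        onset = plan.trial_onset(t)
        try:
            full13, analysis12 = extract_encoding_epoch(
                filtered, onset, tl.encoding_s, tl.word_blank_s
            )
        except ValueError as exc:
            raise RuntimeError(f"signal source underrun at trial {t}: {exc}") from exc
        if mode == "p02":
            full13 = asr_clean(full13, calib, k=config.asr.k, report=cleaning)
            n_lead = int(round(tl.word_blank_s * full13.fs))
            analysis12 = SignalEpoch(
                full13.samples[:, n_lead:].copy(),
                full13.fs,
                full13.channel_labels,
                onset + tl.word_blank_s,
            )
            k_used.append(config.asr.k)
        else:
            k_used.append(None)
        window = full13 if config.use_full_13s else analysis12
        est = welch_psd(window, config.welch)
        power = band_power(est, *config.theta_band)
        band_powers.append(power)
        update_feedback(state, power)

    if responses is None:
        responses = [(None, None)] * plan.n_trials
    scores = score_recognition(responses, plan)
    return NFSessionRecord(
        band_powers=band_powers,
        feedback=state,
        scores=scores,
        k_used=k_used,
        cleaning_report=cleaning,
        responses=list(responses),
        mode=mode,
        config_hash=config_hash(config),
        seed=config.seed,
    )
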