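"""Run-wide configuration: acquisition constants, trial timeline, spectral and
artifact-correction settings.

The defaults describe a 4-contact mesial-temporal montage sampled at 512 Hz
with a 0.5–200 Hz band-pass and a 50 Hz mains notch, and the intermittent
memory-neurofeedback trial timeline: 20 s rest, then per trial a 13-s encoding
period (five words, each shown for 1.6 s after a 1.0-s blank, i.e. a 2.6-s
cycle), two 8-s recognition tasks, and 10 s of bar feedback.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

__all__ = [
    "Timeline",
    "FilterSpec",
    "WelchSettings",
    "ASRPolicy",
    "RunConfig",
    "DEFAULT_CHANNELS",
    "config_hash",
]

DEFAULT_CHANNELS = ("MTL1", "MTL2", "MTL3", "MTL4")


@dataclass(frozen=True)
class Timeline:
    """Trial/session timing in seconds.

    Each word cycle is ``word_blank_s`` of blank screen followed by
    ``word_duration_s`` of word display; with five words this makes the
    encoding period ``n_words * (word_blank_s + word_duration_s)`` = 13 s.
    The analysis window drops the first blank second, leaving 12 s.
    """

    rest_s: float = 20.0
    word_blank_s: float = 1.0
    word_duration_s: float = 1.6
    n_words: int = 5
    task1_s: float = 8.0
    task2_s: float = 8.0
    feedback_s: float = 10.0

    @property
    def word_interval_s(self) -> float:
        return self.word_blank_s + self.word_duration_s

    @property
    def encoding_s(self) -> float:
        return self.n_words * self.word_interval_s

    @property
    def analysis_s(self) -> float:
        return self.encoding_s - self.word_blank_s

    @property
    def trial_s(self) -> float:
        return self.encoding_s + self.task1_s + self.task2_s + self.feedback_s

    def trial_onset(self, trial_index: int) -> float:
        """Onset of the encoding period of ``trial_index`` (0-based)."""
        if trial_index < 0:
            raise IndexError(f"trial_index must be >= 0, got {trial_index}")
        return self.rest_s + trial_index * self.trial_s

    def session_duration(self, n_trials: int) -> float:
        return self.rest_s + n_trials * self.trial_s


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase preprocessing chain: Butterworth band-pass + mains notch."""

    band: tuple[float, float] = (0.5, 200.0)
    notch: float = 50.0
    order: int = 4
    notch_q: float = 30.0

    def validate(self, fs: float) -> None:
        lo, hi = self.band
        if not (0 < lo < hi):
            raise ValueError(f"band edges must satisfy 0 < lo < hi, got {self.band}")
        if hi >= fs / 2:
            raise ValueError(f"band upper edge {hi} Hz >= Nyquist {fs / 2} Hz")
        if not (0 < self.notch < fs / 2):
            raise ValueError(f"notch {self.notch} Hz outside (0, Nyquist)")


@dataclass(frozen=True)
class WelchSettings:
    """Welch periodogram settings: 1-s Hann segments, 50% overlap -> 1 Hz bins."""

    window_s: float = 1.0
    overlap: float = 0.5


@dataclass(frozen=True)
class ASRPolicy:
    """When and how artifact subspace reconstruction is applied.

    mode:
      ``"none"``     — no cleaning (subdural-montage real-time configuration)
      ``"fixed"``    — always clean with cutoff ``k`` (depth-montage real-time
                       configuration, k = 4)
      ``"adaptive"`` — offline rule: k chosen per epoch from the fraction of
                       samples beyond the epoch mean ± 3 SD
                       (< 1% -> 10, 1–1.5% -> 6, > 1.5% -> 4)
    """

    mode: str = "adaptive"
    k: int = 4
    window_s: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("none", "fixed", "adaptive"):
            raise ValueError(f"unknown ASR mode {self.mode!r}")
        if self.k <= 0:
            raise ValueError(f"k must be positive, got {self.k}")


@dataclass(frozen=True)
class RunConfig:
    fs: float = 512.0
    n_channels: int = 4
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS
    theta_band: tuple[float, float] = (4.0, 8.0)
    binwise_band: tuple[float, float] = (1.0, 100.0)
    timeline: Timeline = field(default_factory=Timeline)
    filters: FilterSpec = field(default_factory=FilterSpec)
    welch: WelchSettings = field(default_factory=WelchSettings)
    asr: ASRPolicy = field(default_factory=ASRPolicy)
    use_full_13s: bool = False  # power from the full 13-s epoch instead of 12 s
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length must equal n_channels")
        self.filters.validate(self.fs)

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of a config, embedded in every output artifact."""
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
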