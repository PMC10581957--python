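"""File formats: EDF continuous signals, BIDS-style events TSV, lexicon CSV,
session-plan / ground-truth / record JSON.

EDF writing is implemented directly (16-bit samples, 1-second data records,
physical dimension µV); reading goes through MNE's EDF reader, so the
round-trip doubles as a format-compliance check.
"""

from __future__ import annotations

import json
import struct
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import Timeline
from .paradigm import EVENT_TYPES, Lexicon, SessionPlan, TrialPlan, WordSet
from .realtime import NFSessionRecord
from .synthetic import GroundTruth, SignalEpoch

__all__ = [
    "write_edf",
    "read_edf",
    "write_events",
    "read_events",
    "write_lexicon",
    "read_lexicon",
    "write_plan",
    "read_plan",
    "write_ground_truth",
    "write_record_json",
    "write_metrics_csv",
]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def write_edf(signal: SignalEpoch, path: str | Path, patient: str = "X", recording: str = "thetaloop") -> None:
    """Write a multichannel µV signal as EDF with 1-second data records.

    The signal is zero-padded to a whole number of records; 16-bit
    quantization bounds the round-trip error by the physical range / 2**16.
    """
    path = Path(path)
    fs = signal.fs
    spr = int(round(fs))  # samples per 1-s record
    if abs(spr - fs) > 1e-9:
        raise ValueError(f"EDF writer needs an integer sampling rate, got {fs}")
    n_ch = signal.n_channels
    x = signal.samples
    n_records = int(np.ceil(signal.n_samples / spr))
    padded = np.zeros((n_ch, n_records * spr))
    padded[:, : signal.n_samples] = x

    pmax = float(np.max(np.abs(padded)))
    pmax = float(np.ceil(pmax)) if pmax > 0 else 1.0
    pmin = -pmax
    scale = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
    digital = np.round((padded - pmin) * scale + _DIG_MIN).astype("<i2")

    header = b"".join(
        [
            _ascii("0", 8),
            _ascii(patient, 80),
            _ascii(recording, 80),
            _ascii("01.01.01", 8),
            _ascii("00.00.00", 8),
            _ascii(256 * (1 + n_ch), 8),
            _ascii("", 44),
            _ascii(n_records, 8),
            _ascii("1", 8),  # record duration, s
            _ascii(n_ch, 4),
        ]
    )
    sig_header = b"".join(
        [
            b"".join(_ascii(lbl, 16) for lbl in signal.channel_labels),
            b"".join(_ascii("", 80) for _ in range(n_ch)),  # transducer
            b"".join(_ascii("uV", 8) for _ in range(n_ch)),
            b"".join(_ascii(f"{pmin:g}", 8) for _ in range(n_ch)),
            b"".join(_ascii(f"{pmax:g}", 8) for _ in range(n_ch)),
            b"".join(_ascii(_DIG_MIN, 8) for _ in range(n_ch)),
            b"".join(_ascii(_DIG_MAX, 8) for _ in range(n_ch)),
            b"".join(_ascii("", 80) for _ in range(n_ch)),  # prefiltering
            b"".join(_ascii(spr, 8) for _ in range(n_ch)),
            b"".join(_ascii("", 32) for _ in range(n_ch)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())  # signal-major within each record


def read_edf(path: str | Path) -> SignalEpoch:
    """Read an EDF file into a µV SignalEpoch (via MNE's EDF reader)."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "rb") as fh:
        magic = fh.read(8)
    if not magic.startswith(b"0"):
        raise ValueError(f"malformed EDF header at byte 0: expected version '0', got {magic!r}")
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> µV
    return SignalEpoch(
        samples=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        start_time=0.0,
    )


# ------------------------------------------------------------------- events

def write_events(events: pd.DataFrame, path: str | Path) -> None:
    required = ["onset", "duration", "trial_index", "event_type"]
    if list(events.columns) != required:
        raise ValueError(f"events columns must be {required}")
    _validate_events(events)
    events.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t")
    required = ["onset", "duration", "trial_index", "event_type"]
    if list(events.columns) != required:
        raise ValueError(f"events columns must be {required}, got {list(events.columns)}")
    _validate_events(events)
    return events


def _validate_events(events: pd.DataFrame) -> None:
    bad = set(events["event_type"]) - set(EVENT_TYPES)
    if bad:
        raise ValueError(f"unknown event types {sorted(bad)}; allowed: {EVENT_TYPES}")
    onsets = events["onset"].to_numpy()
    if len(onsets) > 1 and np.any(np.diff(onsets) < -1e-9):
        raise ValueError("event onsets must be non-decreasing")


# ------------------------------------------------------------------ lexicon

def write_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    lexicon.to_frame().to_csv(path, index=False)


def read_lexicon(path: str | Path) -> Lexicon:
    df = pd.read_csv(path)
    return Lexicon(tokens=tuple(df["token"]), familiarity=df["familiarity"].to_numpy(float))


# ------------------------------------------------------------ plans & truth

def write_plan(plan: SessionPlan, path: str | Path) -> None:
    payload = {
        "timeline": asdict(plan.timeline),
        "trials": [
            {
                "words": list(t.word_set.words),
                "mean_familiarity": t.word_set.mean_familiarity,
                "presented": list(t.presented),
                "probe": t.probe,
                "probe_is_old": t.probe_is_old,
                "correct_position": t.correct_position,
            }
            for t in plan.trials
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_plan(path: str | Path) -> SessionPlan:
    payload = json.loads(Path(path).read_text())
    trials = tuple(
        TrialPlan(
            word_set=WordSet(tuple(t["words"]), t["mean_familiarity"]),
            presented=tuple(t["presented"]),
            probe=t["probe"],
            probe_is_old=t["probe_is_old"],
            correct_position=t["correct_position"],
        )
        for t in payload["trials"]
    )
    return SessionPlan(trials=trials, timeline=Timeline(**payload["timeline"]))


def write_ground_truth(gt: GroundTruth, path: str | Path, seed: Optional[int] = None) -> None:
    payload = {
        "theta_factor": gt.theta_factor.tolist(),
        "success": gt.success.astype(bool).tolist(),
        "task2_success": gt.task2_success.astype(bool).tolist(),
        "spike_onsets": gt.spike_onsets.tolist(),
        "spike_onsets_by_trial": [o.tolist() for o in gt.spike_onsets_by_trial],
        "seed": seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


# ------------------------------------------------------------------ records

def write_record_json(record: NFSessionRecord, path: str | Path) -> None:
    payload = {
        "mode": record.mode,
        "config_hash": record.config_hash,
        "seed": record.seed,
        "theta_power": [bp.mean for bp in record.band_powers],
        "log_theta": [bp.log_mean for bp in record.band_powers],
        "per_channel": [list(bp.per_channel) for bp in record.band_powers],
        "bar_heights": record.feedback.bar_heights(),
        "k_used": record.k_used,
        "scores": asdict(record.scores),
        "cleaning": record.cleaning_report.to_dict(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_metrics_csv(record: NFSessionRecord, plan: SessionPlan, path: str | Path) -> None:
    rows = []
    for t, bp in enumerate(record.band_powers):
        a1, a2 = record.responses[t]
        trial = plan.trials[t]
        truth = "old" if trial.probe_is_old else "new"
        rows.append(
            {
                "trial": t,
                "theta_power": bp.mean,
                "log_theta": bp.log_mean,
                "k_used": record.k_used[t],
                "task1_correct": a1 == truth,
                "task2_correct": (
                    a2 == trial.correct_position
                    if trial.probe_is_old and a1 == "old"
                    else None
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
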