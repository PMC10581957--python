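"""Offline statistics battery for theta neurofeedback sessions.

Per-trial spectra are computed with the adaptive artifact-correction rule
(exceedance fraction -> ASR cutoff k), then four analyses run on them:

1. correct-vs-error binwise spectral comparison — per session, the mean dB
   spectrum of correct and of error trials; per frequency bin a paired t-test
   across sessions (sessions lacking either group are excluded), Holm-corrected
   over bins;
2. first-vs-final session binwise comparison — per bin, a Wilcoxon rank-sum
   test between the two sessions' trial dB values, Holm-corrected over bins;
3. one-way ANOVA of log10 theta power across sessions with eta² and
   Tukey-Kramer post-hoc pairs;
4. three session-level Spearman correlations between mean theta power and the
   recognition scores, each on its own trial subset, Holm-corrected over the
   three analyses, with exact-permutation p-values for small session counts.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .asr import ASRCalibration, ASRParams, asr_calibrate, asr_clean, compute_exceedance, select_k
from .config import RunConfig, config_hash
from .paradigm import RecognitionScores, score_recognition
from .realtime import band_power, extract_encoding_epoch, preprocess, welch_psd
from .synthetic import SessionRecording, SignalEpoch

__all__ = [
    "TrialSpectrum",
    "BinwiseTestResult",
    "SessionANOVAResult",
    "TukeyPair",
    "CorrelationResult",
    "StatsReport",
    "InsufficientDataError",
    "holm_bonferroni",
    "spearman_exact",
    "trial_spectrum_from_epoch",
    "psd_per_trial",
    "compare_correct_error",
    "compare_first_final",
    "session_anova",
    "theta_behavior_correlation",
    "analyze",
    "simulate_epoch_spectra",
    "binwise_to_frame",
]

DB_FLOOR = 1e-12  # µV²/Hz floor before the 10*log10 transform


class InsufficientDataError(RuntimeError):
    """Too few usable sessions for a comparison."""


# ----------------------------------------------------------------- containers

@dataclass
class TrialSpectrum:
    session_index: int
    trial_index: int
    freqs: np.ndarray
    psd_db: np.ndarray  # electrode-averaged PSD, 10*log10(µV²/Hz)
    theta_power: float  # electrode-averaged integrated 4–8 Hz power, µV²
    log_theta: float  # log10(theta_power)
    task1_correct: bool
    task2_correct: Optional[bool]  # None outside the task-2 denominator
    probe_is_old: bool
    k_used: Optional[int]
    exceedance: Optional[float] = None


@dataclass
class BinwiseTestResult:
    freqs: np.ndarray
    statistic: np.ndarray
    p_raw: np.ndarray
    p_holm: np.ndarray
    significant: np.ndarray  # adjusted p < alpha
    direction: np.ndarray  # signed effect per bin (dB)
    alpha: float
    test: str
    n_units: int  # paired sessions or pooled trials per side
    detail: dict = field(default_factory=dict)


@dataclass
class TukeyPair:
    group_a: int
    group_b: int
    mean_diff: float  # mean(b) - mean(a)
    p_adj: float
    reject: bool


@dataclass
class SessionANOVAResult:
    f_statistic: float
    df_between: int
    df_within: int
    eta_squared: float
    p_value: float
    group_means: dict[int, float]
    group_sizes: dict[int, int]
    tukey: Optional[list[TukeyPair]]


@dataclass
class CorrelationResult:
    analysis: str  # task1_accuracy | task1_recall | task2_accuracy
    rho: float
    p_raw: float
    p_holm: float
    n: int
    defined: bool
    theta_by_session: dict[int, float] = field(default_factory=dict)
    score_by_session: dict[int, float] = field(default_factory=dict)


@dataclass
class StatsReport:
    correct_error: Optional[BinwiseTestResult]
    correct_error_grouping: Optional[str]
    first_final: BinwiseTestResult
    anova: SessionANOVAResult
    correlations: list[CorrelationResult]
    scores_by_session: dict[int, RecognitionScores]
    k_by_trial: list[Optional[int]]
    config_hash: str
    seed: int

    def to_json(self, indent: int = 2) -> str:
        def convert(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, (np.bool_,)):
                return bool(obj)
            raise TypeError(f"not serializable: {type(obj)}")

        payload = {
            "correct_error": None if self.correct_error is None else asdict(self.correct_error),
            "correct_error_grouping": self.correct_error_grouping,
            "first_final": asdict(self.first_final),
            "anova": asdict(self.anova),
            "correlations": [asdict(c) for c in self.correlations],
            "scores_by_session": {k: asdict(v) for k, v in self.scores_by_session.items()},
            "k_by_trial": self.k_by_trial,
            "config_hash": self.config_hash,
            "seed": self.seed,
        }
        return json.dumps(payload, indent=indent, default=convert)


# ----------------------------------------------------- multiplicity / effect

def holm_bonferroni(pvalues: Sequence[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Step-down Holm adjustment.

    Sort ascending, multiply the i-th smallest by (m - i + 1), enforce
    monotone non-decreasing adjusted values, cap at 1; reject where the
    adjusted p is below alpha.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.array([]), np.array([], dtype=bool)
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return adjusted, adjusted < alpha


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    return float(np.sum(xc * yc) / denom) if denom > 0 else float("nan")


def spearman_exact(x: Sequence[float], y: Sequence[float], max_exact_n: int = 8) -> tuple[float, float]:
    """Spearman rho with an exact two-sided permutation p-value for small n.

    Ties are handled by average ranks; above ``max_exact_n`` the usual
    t-approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 2:
        raise ValueError("need two equal-length series of length >= 2")
    rx = spstats.rankdata(x)
    ry = spstats.rankdata(y)
    rho = _pearson(rx, ry)
    if np.isnan(rho):
        return float("nan"), float("nan")
    if n > max_exact_n:
        return rho, float(spstats.spearmanr(x, y).pvalue)
    count = 0
    total = 0
    target = abs(rho) - 1e-12
    for perm in itertools.permutations(ry):
        total += 1
        if abs(_pearson(rx, np.array(perm))) >= target:
            count += 1
    return rho, count / total


def _eta_squared(groups: list[np.ndarray]) -> tuple[float, float, int, int]:
    """(F, eta², df_between, df_within) by explicit sums of squares."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    dfb = len(groups) - 1
    dfw = len(all_vals) - len(groups)
    if ss_between + ss_within == 0:
        raise ValueError("degenerate data: zero total variance")
    eta2 = ss_between / (ss_between + ss_within)
    if ss_within == 0:
        return float("inf"), eta2, dfb, dfw
    f = (ss_between / dfb) / (ss_within / dfw)
    return float(f), float(eta2), dfb, dfw


# ------------------------------------------------------------ trial spectra

def trial_spectrum_from_epoch(
    full13: SignalEpoch,
    config: RunConfig,
    calibration: Optional[ASRCalibration] = None,
) -> tuple[np.ndarray, np.ndarray, float, Optional[int], float]:
    """Adaptive-ASR spectral pipeline for one encoding epoch.

    Returns (freqs, electrode-averaged dB spectrum, theta power µV²,
    k used or None, exceedance fraction). The epoch is assumed filtered.
    """
    report = compute_exceedance(full13)
    k_used: Optional[int] = None
    epoch = full13
    if config.asr.mode == "adaptive" and calibration is not None:
        k_used = select_k(report.fraction)
        epoch = asr_clean(full13, calibration, k=k_used)
    elif config.asr.mode == "fixed" and calibration is not None:
        k_used = config.asr.k
        epoch = asr_clean(full13, calibration, k=k_used)
    n_lead = int(round(config.timeline.word_blank_s * epoch.fs))
    window = epoch if config.use_full_13s else SignalEpoch(
        epoch.samples[:, n_lead:].copy(), epoch.fs, epoch.channel_labels, epoch.start_time
    )
    est = welch_psd(window, config.welch)
    mean_psd = est.channel_mean()
    psd_db = 10.0 * np.log10(np.maximum(mean_psd, DB_FLOOR))
    theta = band_power(est, *config.theta_band)
    return est.freqs, psd_db, theta.mean, k_used, report.fraction


def psd_per_trial(
    recordings: Sequence[SessionRecording], config: RunConfig | None = None
) -> list[TrialSpectrum]:
    """Run the offline spectral pipeline over full session recordings.

    Per trial: extract the 13-s encoding epoch, measure the exceedance
    fraction, choose k, clean, Welch on the 12-s window, average electrodes.
    ASR calibrates on each session's opening rest period.
    """
    config = config or RunConfig()
    spectra: list[TrialSpectrum] = []
    for rec in recordings:
        plan = rec.plan
        filtered = preprocess(rec.epoch, config.filters)
        calibration = None
        if config.asr.mode != "none":
            rest = filtered.segment(0.0, plan.timeline.rest_s)
            calibration = asr_calibrate(rest, ASRParams(window_s=config.asr.window_s))
        for t in range(plan.n_trials):
            try:
                full13, _ = extract_encoding_epoch(
                    filtered, plan.trial_onset(t), plan.timeline.encoding_s, plan.timeline.word_blank_s
                )
                freqs, psd_db, theta, k_used, frac = trial_spectrum_from_epoch(
                    full13, config, calibration
                )
            except Exception as exc:
                raise RuntimeError(
                    f"session {rec.session_index} trial {t}: {exc}"
                ) from exc
            trial = plan.trials[t]
            a1, a2 = rec.responses[t]
            truth = "old" if trial.probe_is_old else "new"
            t1_ok = a1 == truth
            t2_ok: Optional[bool] = None
            if trial.probe_is_old and a1 == "old":
                t2_ok = a2 == trial.correct_position
            spectra.append(
                TrialSpectrum(
                    session_index=rec.session_index,
                    trial_index=t,
                    freqs=freqs,
                    psd_db=psd_db,
                    theta_power=theta,
                    log_theta=float(np.log10(theta)) if theta > 0 else float("-inf"),
                    task1_correct=t1_ok,
                    task2_correct=t2_ok,
                    probe_is_old=trial.probe_is_old,
                    k_used=k_used,
                    exceedance=frac,
                )
            )
    return spectra


def _band_mask(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    return (freqs >= band[0]) & (freqs <= band[1])


def _sessions(spectra: Sequence[TrialSpectrum]) -> list[int]:
    return sorted({s.session_index for s in spectra})


# ------------------------------------------------------------- binwise tests

def compare_correct_error(
    spectra: Sequence[TrialSpectrum],
    grouping: str = "task1",
    alpha: float = 0.05,
    band: tuple[float, float] = (1.0, 100.0),
) -> BinwiseTestResult:
    """Correct-vs-error spectral comparison, paired over sessions.

    Each usable session contributes one mean correct-trial dB spectrum and
    one mean error-trial dB spectrum; sessions in which every trial (or no
    trial) was answered correctly under ``grouping`` are excluded. Per bin a
    paired t-test runs across sessions, Holm-corrected over bins.
    """
    if grouping not in ("task1", "task2"):
        raise ValueError("grouping must be 'task1' or 'task2'")

    def flag(s: TrialSpectrum) -> Optional[bool]:
        return s.task1_correct if grouping == "task1" else s.task2_correct

    freqs = spectra[0].freqs
    mask = _band_mask(freqs, band)
    correct_means, error_means, used = [], [], []
    for sess in _sessions(spectra):
        trials = [s for s in spectra if s.session_index == sess and flag(s) is not None]
        corr = [s.psd_db[mask] for s in trials if flag(s)]
        err = [s.psd_db[mask] for s in trials if flag(s) is False]
        if corr and err:
            correct_means.append(np.mean(corr, axis=0))
            error_means.append(np.mean(err, axis=0))
            used.append(sess)
    if len(used) < 2:
        raise InsufficientDataError(
            f"only {len(used)} session(s) have both correct and error trials "
            f"under grouping {grouping!r}; need >= 2"
        )
    C = np.array(correct_means)
    E = np.array(error_means)
    t_stat, p_raw = spstats.ttest_rel(C, E, axis=0)
    p_raw = np.nan_to_num(p_raw, nan=1.0)
    p_holm, reject = holm_bonferroni(p_raw, alpha)
    return BinwiseTestResult(
        freqs=freqs[mask],
        statistic=np.asarray(t_stat),
        p_raw=p_raw,
        p_holm=p_holm,
        significant=reject,
        direction=(C - E).mean(axis=0),
        alpha=alpha,
        test=f"paired t (correct-error, {grouping})",
        n_units=len(used),
        detail={"sessions_used": used, "grouping": grouping},
    )


def compare_first_final(
    spectra: Sequence[TrialSpectrum],
    alpha: float = 0.05,
    band: tuple[float, float] = (1.0, 100.0),
) -> BinwiseTestResult:
    """First-vs-final session spectral comparison (Wilcoxon rank-sum per bin).

    Direction is the median dB difference final - first. Handles unequal trial
    counts (truncated sessions)."""
    sess = _sessions(spectra)
    if len(sess) < 2:
        raise InsufficientDataError("need at least 2 sessions")
    first = [s for s in spectra if s.session_index == sess[0]]
    final = [s for s in spectra if s.session_index == sess[-1]]
    if len(first) < 2 or len(final) < 2:
        raise ValueError("each compared session needs >= 2 trials")
    freqs = spectra[0].freqs
    mask = _band_mask(freqs, band)
    A = np.array([s.psd_db[mask] for s in first])
    B = np.array([s.psd_db[mask] for s in final])
    stat = np.empty(A.shape[1])
    p_raw = np.empty(A.shape[1])
    for j in range(A.shape[1]):
        res = spstats.ranksums(B[:, j], A[:, j])
        stat[j], p_raw[j] = res.statistic, res.pvalue
    p_holm, reject = holm_bonferroni(p_raw, alpha)
    return BinwiseTestResult(
        freqs=freqs[mask],
        statistic=stat,
        p_raw=p_raw,
        p_holm=p_holm,
        significant=reject,
        direction=np.median(B, axis=0) - np.median(A, axis=0),
        alpha=alpha,
        test="Wilcoxon rank-sum (final - first)",
        n_units=len(first) + len(final),
        detail={"first_session": sess[0], "final_session": sess[-1],
                "n_first": len(first), "n_final": len(final)},
    )


# ------------------------------------------------------------------- ANOVA

def session_anova(
    log_theta_by_session: dict[int, np.ndarray] | Sequence[np.ndarray],
    alpha: float = 0.05,
) -> SessionANOVAResult:
    """One-way ANOVA of per-trial log10 theta power across sessions, with
    eta² = SS_between / SS_total and Tukey-Kramer all-pairs post-hoc."""
    if isinstance(log_theta_by_session, dict):
        keys = sorted(log_theta_by_session)
        groups = [np.asarray(log_theta_by_session[k], dtype=float) for k in keys]
    else:
        keys = list(range(len(log_theta_by_session)))
        groups = [np.asarray(g, dtype=float) for g in log_theta_by_session]
    if len(groups) < 2:
        raise ValueError("need >= 2 sessions")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every session needs >= 2 trials")
    f, eta2, dfb, dfw = _eta_squared(groups)
    p = float(spstats.f.sf(f, dfb, dfw)) if np.isfinite(f) else 0.0

    tukey: Optional[list[TukeyPair]] = None
    if np.isfinite(f):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        endog = np.concatenate(groups)
        labels = np.concatenate([[k] * len(g) for k, g in zip(keys, groups)])
        res = pairwise_tukeyhsd(endog, labels, alpha=alpha)
        pairs = list(itertools.combinations(res.groupsunique, 2))
        tukey = [
            TukeyPair(int(a), int(b), float(diff), float(p_adj), bool(rej))
            for (a, b), diff, p_adj, rej in zip(
                pairs, res.meandiffs, res.pvalues, res.reject
            )
        ]
    return SessionANOVAResult(
        f_statistic=f,
        df_between=dfb,
        df_within=dfw,
        eta_squared=eta2,
        p_value=p,
        group_means={k: float(g.mean()) for k, g in zip(keys, groups)},
        group_sizes={k: len(g) for k, g in zip(keys, groups)},
        tukey=tukey,
    )


# -------------------------------------------------------------- correlations

def theta_behavior_correlation(
    spectra: Sequence[TrialSpectrum],
    scores_by_session: dict[int, RecognitionScores],
    alpha: float = 0.05,
) -> list[CorrelationResult]:
    """Three session-level Spearman correlations with subset rules:

    - mean theta of ALL trials vs task-1 accuracy;
    - mean theta of old-probe trials vs task-1 recall;
    - mean theta of trials correctly answered "old" vs task-2 accuracy.

    Undefined correlations (constant series, or too few sessions with a
    defined score) are flagged and excluded from the Holm family.
    """
    sessions = _sessions(spectra)
    if len(sessions) < 4:
        raise InsufficientDataError("need >= 4 sessions for correlation analysis")

    def mean_theta(sess: int, predicate) -> Optional[float]:
        vals = [s.theta_power for s in spectra if s.session_index == sess and predicate(s)]
        return float(np.mean(vals)) if vals else None

    specs = [
        ("task1_accuracy", lambda s: True, lambda sc: sc.task1_accuracy),
        ("task1_recall", lambda s: s.probe_is_old, lambda sc: sc.task1_recall),
        ("task2_accuracy", lambda s: s.task2_correct is not None, lambda sc: sc.task2_accuracy),
    ]
    results: list[CorrelationResult] = []
    for name, predicate, score_of in specs:
        theta, score, sess_used = [], [], []
        for sess in sessions:
            th = mean_theta(sess, predicate)
            sc = score_of(scores_by_session[sess])
            if th is not None and sc is not None:
                theta.append(th)
                score.append(float(sc))
                sess_used.append(sess)
        defined = len(theta) >= 4 and np.std(theta) > 0 and np.std(score) > 0
        if defined:
            rho, p = spearman_exact(theta, score)
            defined = not np.isnan(rho)
        if not defined:
            rho, p = float("nan"), float("nan")
        results.append(
            CorrelationResult(
                analysis=name,
                rho=rho,
                p_raw=p,
                p_holm=float("nan"),
                n=len(theta),
                defined=defined,
                theta_by_session=dict(zip(sess_used, theta)),
                score_by_session=dict(zip(sess_used, score)),
            )
        )
    family = [r for r in results if r.defined]
    if family:
        adj, _ = holm_bonferroni([r.p_raw for r in family], alpha)
        for r, a in zip(family, adj):
            r.p_holm = float(a)
    return results


# ----------------------------------------------------------------- top level

def analyze(
    recordings: Sequence[SessionRecording], config: RunConfig | None = None
) -> StatsReport:
    """Full offline battery over a set of session recordings.

    The correct/error comparison first tries task-1 grouping and falls back
    to task-2 grouping when too few sessions contain task-1 errors (ceiling
    performance), mirroring how high recognition accuracy forces the analysis
    onto the harder task.
    """
    config = config or RunConfig()
    spectra = psd_per_trial(recordings, config)
    scores = {
        rec.session_index: score_recognition(rec.responses, rec.plan) for rec in recordings
    }
    ce: Optional[BinwiseTestResult] = None
    grouping: Optional[str] = None
    for candidate in ("task1", "task2"):
        try:
            ce = compare_correct_error(spectra, candidate, config.alpha, config.binwise_band)
            grouping = candidate
            break
        except InsufficientDataError:
            continue
    ff = compare_first_final(spectra, config.alpha, config.binwise_band)
    by_session: dict[int, list[float]] = {}
    for s in spectra:
        by_session.setdefault(s.session_index, []).append(s.log_theta)
    anova = session_anova({k: np.array(v) for k, v in by_session.items()}, config.alpha)
    correlations = theta_behavior_correlation(spectra, scores, config.alpha)
    return StatsReport(
        correct_error=ce,
        correct_error_grouping=grouping,
        first_final=ff,
        anova=anova,
        correlations=correlations,
        scores_by_session=scores,
        k_by_trial=[s.k_used for s in spectra],
        config_hash=config_hash(config),
        seed=config.seed,
    )


def simulate_epoch_spectra(
    plans: Sequence,
    learner,
    noise,
    osc,
    spikes,
    seed: int,
    config: RunConfig | None = None,
) -> tuple[list[TrialSpectrum], dict[int, RecognitionScores]]:
    """Monte-Carlo fast path: generate encoding epochs (plus a per-session
    calibration rest epoch) directly instead of full continuous sessions.

    The offline battery consumes only encoding epochs, so this is exact for
    the statistics while skipping the task/feedback/rest signal in between.
    Returns the trial spectra and per-session recognition scores.
    """
    from .synthetic import (
        OscillationSpec,
        _scheduled_success,
        add_oscillation,
        generate_background,
        inject_spikes,
        simulate_responses,
        GroundTruth,
    )

    config = config or RunConfig()
    spectra: list[TrialSpectrum] = []
    scores: dict[int, RecognitionScores] = {}
    root = np.random.SeedSequence(seed)
    for s, plan in enumerate(plans):
        ss = np.random.SeedSequence([seed, s])
        seeds = ss.generate_state(4 + 2 * plan.n_trials)
        rng = np.random.default_rng(int(seeds[0]))
        gain = learner.theta_gain_by_session[s]
        jitter = np.exp(learner.jitter_sigma * rng.standard_normal(plan.n_trials))
        theta_factor = gain * jitter

        # calibration reference: rest-like segment with baseline theta
        rest = generate_background(plan.timeline.rest_s, config.fs, noise, int(seeds[1]))
        rest = add_oscillation(rest, osc, int(seeds[2]))
        if spikes is not None and spikes.rate > 0:
            rest, _ = inject_spikes(rest, spikes, int(seeds[3]))
        rest = preprocess(rest, config.filters)
        calibration = None
        if config.asr.mode != "none":
            calibration = asr_calibrate(rest, ASRParams(window_s=config.asr.window_s))

        success, task2 = _scheduled_success(learner, theta_factor, rng)
        for t in range(plan.n_trials):
            epoch = generate_background(
                plan.timeline.encoding_s, config.fs, noise, int(seeds[4 + 2 * t])
            )
            scaled = OscillationSpec(osc.center_freq, osc.bandwidth, osc.amplitude * theta_factor[t])
            epoch = add_oscillation(epoch, scaled, int(seeds[5 + 2 * t]))
            if spikes is not None and spikes.rate > 0:
                epoch, _ = inject_spikes(
                    epoch, spikes, int(np.random.SeedSequence([seed, s, 7001 + t]).generate_state(1)[0])
                )
            epoch = preprocess(epoch, config.filters)
            freqs, psd_db, theta, k_used, frac = trial_spectrum_from_epoch(epoch, config, calibration)
            trial = plan.trials[t]
            spectra.append(
                TrialSpectrum(
                    session_index=s,
                    trial_index=t,
                    freqs=freqs,
                    psd_db=psd_db,
                    theta_power=theta,
                    log_theta=float(np.log10(theta)),
                    task1_correct=bool(success[t]),
                    task2_correct=(
                        bool(task2[t]) if trial.probe_is_old and success[t] else None
                    ),
                    probe_is_old=trial.probe_is_old,
                    k_used=k_used,
                    exceedance=frac,
                )
            )
        gt = GroundTruth(theta_factor, success, task2, np.array([]), [])
        responses = simulate_responses(plan, gt, int(root.generate_state(1)[0]) + s)
        scores[s] = score_recognition(responses, plan)
    return spectra, scores


def binwise_to_frame(result: BinwiseTestResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "freq": result.freqs,
            "stat": result.statistic,
            "p_raw": result.p_raw,
            "p_holm": result.p_holm,
            "significant": result.significant,
            "direction": result.direction,
        }
    )
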