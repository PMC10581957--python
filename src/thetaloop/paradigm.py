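"""Old/new recognition memory task: familiarity-balanced six-word sets,
per-session trial schedules, the trial timeline as an event table, and
recognition scoring.

A trial presents five of a set's six words during encoding. The probe in the
recognition period is either one of the five presented words (an *old* probe;
task 2 then asks at which position, 1–5, it appeared) or the held-out sixth
word (a *new* probe). A default session has 20 trials, 10 old and 10 new, in
randomized order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import Timeline

__all__ = [
    "Lexicon",
    "WordSet",
    "TrialPlan",
    "SessionPlan",
    "RecognitionScores",
    "BalancingError",
    "build_lexicon",
    "make_word_sets",
    "schedule_session",
    "trial_events",
    "session_events",
    "score_recognition",
    "truncate_session",
]

EVENT_TYPES = ("rest", "word", "probe_task1", "probe_task2", "feedback")


class BalancingError(RuntimeError):
    """Familiarity balancing did not reach tolerance; carries the best spread."""

    def __init__(self, message: str, best_spread: float):
        super().__init__(message)
        self.best_spread = best_spread


@dataclass(frozen=True)
class Lexicon:
    tokens: tuple[str, ...]
    familiarity: np.ndarray  # one score per token

    def __post_init__(self) -> None:
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("lexicon tokens must be unique")
        if len(self.tokens) != len(self.familiarity):
            raise ValueError("tokens and familiarity lengths differ")
        if not np.all(np.isfinite(self.familiarity)):
            raise ValueError("familiarity scores must be finite")

    def __len__(self) -> int:
        return len(self.tokens)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"token": self.tokens, "familiarity": self.familiarity})


@dataclass(frozen=True)
class WordSet:
    words: tuple[str, ...]  # exactly 6 distinct tokens
    mean_familiarity: float

    def __post_init__(self) -> None:
        if len(self.words) != 6 or len(set(self.words)) != 6:
            raise ValueError("a word set holds exactly 6 distinct words")


@dataclass(frozen=True)
class TrialPlan:
    word_set: WordSet
    presented: tuple[str, ...]  # ordered, 5 of the 6
    probe: str
    probe_is_old: bool
    correct_position: Optional[int]  # 1..5 when probe_is_old, else None

    def __post_init__(self) -> None:
        if len(self.presented) != 5 or not set(self.presented) <= set(self.word_set.words):
            raise ValueError("presented must be 5 words drawn from the word set")
        if self.probe_is_old != (self.probe in self.presented):
            raise ValueError("probe_is_old inconsistent with probe membership")
        if self.probe_is_old:
            if self.correct_position != self.presented.index(self.probe) + 1:
                raise ValueError("correct_position inconsistent with presented order")
        elif self.correct_position is not None:
            raise ValueError("correct_position must be None for new probes")


@dataclass(frozen=True)
class SessionPlan:
    trials: tuple[TrialPlan, ...]
    timeline: Timeline = field(default_factory=Timeline)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_old(self) -> int:
        return sum(t.probe_is_old for t in self.trials)

    @property
    def duration_s(self) -> float:
        return self.timeline.session_duration(self.n_trials)

    def trial_onset(self, trial_index: int) -> float:
        if not 0 <= trial_index < self.n_trials:
            raise IndexError(f"trial_index {trial_index} out of range 0..{self.n_trials - 1}")
        return self.timeline.trial_onset(trial_index)


@dataclass(frozen=True)
class RecognitionScores:
    """Session-level scores in percent.

    ``task2_accuracy`` is computed only over old probes answered correctly as
    old in task 1; when that denominator is zero the score is undefined
    (``None``) rather than 0.
    """

    task1_accuracy: float
    task1_recall: float
    task2_accuracy: Optional[float]
    n_trials: int
    n_old: int
    task2_denominator: int


def build_lexicon(
    n_words: int, familiarity_mean: float = 5.0, familiarity_sd: float = 1.0, seed: int = 0
) -> Lexicon:
    """Synthetic token lexicon with Gaussian familiarity scores.

    Stands in for a large familiarity-rated word database; tokens are opaque
    strings (``w000001`` ...).
    """
    if n_words < 6:
        raise ValueError(f"need at least 6 words, got {n_words}")
    if familiarity_sd < 0:
        raise ValueError("familiarity_sd must be >= 0")
    rng = np.random.default_rng(seed)
    tokens = tuple(f"w{i:06d}" for i in range(n_words))
    fam = familiarity_mean + familiarity_sd * rng.standard_normal(n_words)
    return Lexicon(tokens=tokens, familiarity=fam)


def _set_means(fam: np.ndarray, assignment: np.ndarray, n_sets: int) -> np.ndarray:
    means = np.empty(n_sets)
    for s in range(n_sets):
        means[s] = fam[assignment == s].mean()
    return means


def make_word_sets(
    lexicon: Lexicon,
    n_sets: int,
    tolerance: Optional[float] = None,
    seed: int = 0,
    max_iter: int = 20000,
) -> list[WordSet]:
    """Partition ``6 * n_sets`` words into disjoint six-word sets with equal
    mean familiarity.

    Greedy snake-deal over familiarity-sorted words, then pairwise swap
    refinement until every set mean lies within ``tolerance`` of the grand
    mean. Default tolerance is 0.05 SD of the lexicon familiarity.

    Raises :class:`BalancingError` if tolerance is not reached in ``max_iter``
    swap attempts.
    """
    need = 6 * n_sets
    if len(lexicon) < need:
        raise ValueError(f"lexicon has {len(lexicon)} words; {need} required")
    rng = np.random.default_rng(seed)
    fam_all = np.asarray(lexicon.familiarity, dtype=float)
    if tolerance is None:
        sd = float(fam_all.std())
        tolerance = 0.05 * sd if sd > 0 else 0.0

    # sample the words to use, then snake-deal by descending familiarity
    idx = rng.choice(len(lexicon), size=need, replace=False)
    fam = fam_all[idx]
    order = np.argsort(fam)[::-1]
    assignment = np.empty(need, dtype=int)
    for row in range(6):
        block = order[row * n_sets : (row + 1) * n_sets]
        cols = np.arange(n_sets) if row % 2 == 0 else np.arange(n_sets)[::-1]
        assignment[block] = cols

    grand = fam.mean()
    means = _set_means(fam, assignment, n_sets)

    def spread() -> float:
        return float(np.max(np.abs(means - grand)))

    it = 0
    while spread() > tolerance and it < max_iter:
        it += 1
        hi = int(np.argmax(means - grand))
        lo = int(np.argmin(means - grand))
        # best single swap between the most extreme sets
        hi_members = np.flatnonzero(assignment == hi)
        lo_members = np.flatnonzero(assignment == lo)
        diff = means[hi] - means[lo]
        delta = fam[hi_members][:, None] - fam[lo_members][None, :]
        # swapping changes each mean by -+ delta/6; ideal delta = 3*diff... pick
        # the pair bringing both means closest to the grand mean
        target = 3.0 * diff
        best = np.unravel_index(np.argmin(np.abs(delta - target)), delta.shape)
        a, b = hi_members[best[0]], lo_members[best[1]]
        d = fam[a] - fam[b]
        if abs(d) < 1e-15 or abs(delta[best] - target) >= abs(0.0 - target):
            # no helpful swap between extremes: random perturbation
            a = int(rng.choice(hi_members))
            b = int(rng.choice(lo_members))
            d = fam[a] - fam[b]
        assignment[a], assignment[b] = assignment[b], assignment[a]
        means[hi] -= d / 6.0
        means[lo] += d / 6.0

    if spread() > tolerance:
        raise BalancingError(
            f"could not balance {n_sets} sets to ±{tolerance:.4g} "
            f"(best spread {spread():.4g}) in {max_iter} iterations",
            best_spread=spread(),
        )

    sets = []
    for s in range(n_sets):
        members = idx[assignment == s]
        words = tuple(lexicon.tokens[i] for i in members)
        sets.append(WordSet(words=words, mean_familiarity=float(fam_all[members].mean())))
    return sets


def schedule_session(
    word_sets: Sequence[WordSet],
    n_old: int = 10,
    n_new: int = 10,
    seed: int = 0,
    timeline: Optional[Timeline] = None,
) -> SessionPlan:
    """Build a session: one word set per trial, old/new assignment shuffled.

    Each trial presents 5 of its set's 6 words in random order. Old trials
    probe one presented word (uniform over the five positions); new trials
    probe the held-out word.
    """
    if len(word_sets) != n_old + n_new:
        raise ValueError(f"{len(word_sets)} word sets but n_old + n_new = {n_old + n_new}")
    rng = np.random.default_rng(seed)
    is_old = np.array([True] * n_old + [False] * n_new)
    rng.shuffle(is_old)
    trials = []
    for ws, old in zip(word_sets, is_old):
        words = np.array(ws.words)
        perm = rng.permutation(6)
        presented = tuple(words[perm[:5]])
        held_out = words[perm[5]]
        if old:
            pos = int(rng.integers(5))  # 0-based position of the probe
            trials.append(
                TrialPlan(
                    word_set=ws,
                    presented=presented,
                    probe=presented[pos],
                    probe_is_old=True,
                    correct_position=pos + 1,
                )
            )
        else:
            trials.append(
                TrialPlan(
                    word_set=ws,
                    presented=presented,
                    probe=str(held_out),
                    probe_is_old=False,
                    correct_position=None,
                )
            )
    return SessionPlan(trials=tuple(trials), timeline=timeline or Timeline())


def truncate_session(plan: SessionPlan, n_trials: int) -> SessionPlan:
    """Cut a session after ``n_trials`` trials (aborted-session support)."""
    if not 0 < n_trials <= plan.n_trials:
        raise ValueError(f"n_trials must be in 1..{plan.n_trials}")
    return replace(plan, trials=plan.trials[:n_trials])


def trial_events(plan: SessionPlan, trial_index: int) -> pd.DataFrame:
    """Event table (onset, duration, trial_index, event_type) for one trial.

    The first trial is preceded by the session's rest period.
    """
    tl = plan.timeline
    t0 = plan.trial_onset(trial_index)
    rows = []
    if trial_index == 0:
        rows.append((0.0, tl.rest_s, -1, "rest"))
    for k in range(tl.n_words):
        rows.append((t0 + tl.word_blank_s + k * tl.word_interval_s, tl.word_duration_s, trial_index, "word"))
    t = t0 + tl.encoding_s
    rows.append((t, tl.task1_s, trial_index, "probe_task1"))
    rows.append((t + tl.task1_s, tl.task2_s, trial_index, "probe_task2"))
    rows.append((t + tl.task1_s + tl.task2_s, tl.feedback_s, trial_index, "feedback"))
    return pd.DataFrame(rows, columns=["onset", "duration", "trial_index", "event_type"])


def session_events(plan: SessionPlan) -> pd.DataFrame:
    parts = [trial_events(plan, i) for i in range(plan.n_trials)]
    return pd.concat(parts, ignore_index=True)


def score_recognition(
    responses: Sequence[tuple[Optional[str], Optional[int]]], plan: SessionPlan
) -> RecognitionScores:
    """Score a session from (task1_answer, task2_answer) pairs.

    ``task1_answer`` is ``"old"``/``"new"`` (``None`` = no response, counted
    incorrect); ``task2_answer`` is a position 1..5 or ``None``. Task 2 is only
    scored on old probes answered correctly as old in task 1.
    """
    if len(responses) != plan.n_trials:
        raise ValueError(f"{len(responses)} responses for {plan.n_trials} trials")
    n = plan.n_trials
    n_old = plan.n_old
    t1_correct = 0
    hits = 0  # old probes answered "old"
    t2_denominator = 0
    t2_correct = 0
    for (a1, a2), trial in zip(responses, plan.trials):
        truth = "old" if trial.probe_is_old else "new"
        if a1 == truth:
            t1_correct += 1
        if trial.probe_is_old and a1 == "old":
            hits += 1
            t2_denominator += 1
            if a2 == trial.correct_position:
                t2_correct += 1
    return RecognitionScores(
        task1_accuracy=100.0 * t1_correct / n,
        task1_recall=100.0 * hits / n_old if n_old else 0.0,
        task2_accuracy=100.0 * t2_correct / t2_denominator if t2_denominator else None,
        n_trials=n,
        n_old=n_old,
        task2_denominator=t2_denominator,
    )
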