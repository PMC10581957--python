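"""Shared fixtures: a balanced lexicon, word sets, and session plans.

Plans are deterministic given their seeds and are reused across tests;
signal-level randomness always comes from per-test seeds.
"""

import numpy as np
import pytest

from thetaloop import (
    LearnerModel,
    NoiseModel,
    OscillationSpec,
    build_lexicon,
    make_word_sets,
    schedule_session,
)


@pytest.fixture(scope="session")
def lexicon():
    return build_lexicon(800, seed=11)


@pytest.fixture(scope="session")
def word_sets_20(lexicon):
    return make_word_sets(lexicon, 20, seed=3)


@pytest.fixture(scope="session")
def plan20(word_sets_20):
    """One default 20-trial session (10 old, 10 new)."""
    return schedule_session(word_sets_20, seed=5)


@pytest.fixture(scope="session")
def plans6(lexicon):
    """Six 20-trial session plans over disjoint word sets."""
    sets = make_word_sets(lexicon, 120, seed=4)
    return [
        schedule_session(sets[20 * s : 20 * (s + 1)], seed=50 + s) for s in range(6)
    ]


@pytest.fixture(scope="session")
def plans4_small(lexicon):
    """Four 6-trial sessions (3 old / 3 new) for fast end-to-end runs."""
    sets = make_word_sets(lexicon, 24, seed=9)
    return [
        schedule_session(sets[6 * s : 6 * (s + 1)], n_old=3, n_new=3, seed=70 + s)
        for s in range(4)
    ]


@pytest.fixture(scope="session")
def flat_learner():
    return LearnerModel()


@pytest.fixture(scope="session")
def default_noise():
    return NoiseModel()


@pytest.fixture(scope="session")
def default_osc():
    return OscillationSpec()
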