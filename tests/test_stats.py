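"""Offline statistics battery: Holm step-down, exact Spearman, ANOVA with
eta-squared and Tukey pairs, the binwise spectral comparisons, and the
session-level correlations."""

import itertools

import numpy as np
import pytest
from scipy import stats as spstats

from thetaloop import (
    InsufficientDataError,
    LearnerModel,
    NoiseModel,
    OscillationSpec,
    RunConfig,
    analyze,
    compare_correct_error,
    compare_first_final,
    generate_experiment,
    holm_bonferroni,
    session_anova,
    simulate_epoch_spectra,
    spearman_exact,
    theta_behavior_correlation,
)
from thetaloop.paradigm import RecognitionScores
from thetaloop.stats import TrialSpectrum, binwise_to_frame


# ------------------------------------------------------------------- Holm

def test_holm_hand_worked_example():
    adjusted, reject = holm_bonferroni([0.01, 0.04, 0.03], alpha=0.05)
    assert np.allclose(adjusted, [0.03, 0.06, 0.06])
    assert list(reject) == [True, False, False]


def test_holm_single_p_and_all_zero():
    adjusted, reject = holm_bonferroni([0.2])
    assert adjusted[0] == pytest.approx(0.2)
    adjusted, reject = holm_bonferroni([0.0, 0.0, 0.0])
    assert np.all(reject)
    adjusted, reject = holm_bonferroni([])
    assert adjusted.size == 0


def test_holm_rejects_out_of_range_p():
    with pytest.raises(ValueError):
        holm_bonferroni([0.5, 1.2])
    with pytest.raises(ValueError):
        holm_bonferroni([-0.1])


def test_holm_matches_statsmodels_on_random_vectors():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(42)
    for _ in range(20):
        p = rng.uniform(size=rng.integers(1, 40))
        adjusted, reject = holm_bonferroni(p, alpha=0.05)
        sm_reject, sm_adjusted, _, _ = multipletests(p, alpha=0.05, method="holm")
        assert np.allclose(adjusted, sm_adjusted, atol=1e-12)
        assert np.array_equal(reject, sm_reject)


def test_holm_dominates_bonferroni():
    rng = np.random.default_rng(43)
    for _ in range(50):
        p = rng.uniform(size=rng.integers(2, 30))
        _, holm_reject = holm_bonferroni(p, alpha=0.05)
        bonf_reject = p * len(p) < 0.05
        assert np.all(holm_reject[bonf_reject])


# ----------------------------------------------------------------- Spearman

def test_spearman_perfect_monotone_series():
    rho, p = spearman_exact([1, 2, 3, 4, 5, 6], [10, 20, 25, 40, 41, 90])
    assert rho == pytest.approx(1.0)
    assert p == pytest.approx(2 / 720)  # both extreme orderings of 6! permutations
    rho, _ = spearman_exact([1, 2, 3, 4], [5, 4, 3, 2])
    assert rho == pytest.approx(-1.0)


def _brute_force_spearman_p(x, y):
    rx = spstats.rankdata(x)
    ry = spstats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    hits = 0
    perms = list(itertools.permutations(ry))
    for perm in perms:
        if abs(np.corrcoef(rx, np.array(perm))[0, 1]) >= obs - 1e-12:
            hits += 1
    return hits / len(perms)


def test_spearman_exact_p_matches_enumeration_oracle():
    rng = np.random.default_rng(44)
    for n in (4, 5, 6):
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        rho, p = spearman_exact(x, y)
        assert rho == pytest.approx(float(spstats.spearmanr(x, y).statistic), abs=1e-10)
        assert p == pytest.approx(_brute_force_spearman_p(x, y), abs=1e-12)


def test_spearman_large_n_uses_t_approximation():
    rng = np.random.default_rng(45)
    x = rng.normal(size=20)
    y = rng.normal(size=20)
    rho, p = spearman_exact(x, y)
    ref = spstats.spearmanr(x, y)
    assert rho == pytest.approx(float(ref.statistic), abs=1e-10)
    assert p == pytest.approx(float(ref.pvalue), abs=1e-10)


def test_spearman_validation():
    with pytest.raises(ValueError):
        spearman_exact([1.0], [2.0])
    with pytest.raises(ValueError):
        spearman_exact([1, 2, 3], [1, 2])


# -------------------------------------------------------------------- ANOVA

def test_anova_matches_scipy_on_random_groups():
    rng = np.random.default_rng(46)
    for _ in range(20):
        groups = [rng.normal(loc=rng.normal(), size=rng.integers(3, 15)) for _ in range(rng.integers(2, 6))]
        res = session_anova(groups)
        ref = spstats.f_oneway(*groups)
        assert res.f_statistic == pytest.approx(float(ref.statistic), abs=1e-10)
        assert res.p_value == pytest.approx(float(ref.pvalue), abs=1e-10)
        ss_total = np.sum((np.concatenate(groups) - np.concatenate(groups).mean()) ** 2)
        ss_within = sum(np.sum((g - g.mean()) ** 2) for g in groups)
        assert res.eta_squared == pytest.approx(1 - ss_within / ss_total, abs=1e-10)


def test_anova_eta_squared_limit_with_zero_within_variance():
    groups = [np.full(5, 1.0), np.full(5, 2.0), np.full(5, 3.0)]
    res = session_anova(groups)
    assert res.eta_squared == pytest.approx(1.0)
    assert np.isinf(res.f_statistic)
    assert res.p_value == 0.0


def test_anova_validation():
    with pytest.raises(ValueError):
        session_anova([np.zeros(5)])
    with pytest.raises(ValueError):
        session_anova([np.zeros(5), np.array([1.0])])
    with pytest.raises(ValueError):
        session_anova([np.full(5, 2.0), np.full(5, 2.0)])  # zero total variance


def test_anova_tukey_detects_shifted_group():
    rng = np.random.default_rng(47)
    groups = {0: rng.normal(0, 0.3, 20), 1: rng.normal(0, 0.3, 20), 2: rng.normal(3, 0.3, 20)}
    res = session_anova(groups)
    flags = {(t.group_a, t.group_b): t for t in res.tukey}
    assert flags[(0, 2)].reject and flags[(1, 2)].reject
    assert not flags[(0, 1)].reject
    assert flags[(0, 2)].mean_diff == pytest.approx(groups[2].mean() - groups[0].mean(), abs=1e-9)


# ------------------------------------------------- binwise comparison tests

FREQS = np.arange(1.0, 101.0)


def _spectrum(session, trial, psd_db, correct=True, task2=None, old=True):
    return TrialSpectrum(
        session_index=session,
        trial_index=trial,
        freqs=FREQS,
        psd_db=np.asarray(psd_db, dtype=float),
        theta_power=1.0,
        log_theta=0.0,
        task1_correct=correct,
        task2_correct=task2,
        probe_is_old=old,
        k_used=None,
    )


def test_correct_error_identical_spectra_gives_no_significance():
    base = np.linspace(10, -20, len(FREQS))
    spectra = []
    for s in range(4):
        for t in range(6):
            spectra.append(_spectrum(s, t, base, correct=(t % 2 == 0)))
    res = compare_correct_error(spectra)
    assert np.allclose(res.p_raw, 1.0)
    assert not np.any(res.significant)
    assert res.n_units == 4


def test_correct_error_excludes_sessions_without_both_outcomes():
    rng = np.random.default_rng(48)
    spectra = []
    for s in range(6):
        for t in range(6):
            correct = True if s == 0 else (t % 2 == 0)  # session 0 is all-correct
            spectra.append(_spectrum(s, t, rng.normal(size=len(FREQS)), correct=correct))
    res = compare_correct_error(spectra)
    assert res.n_units == 5
    assert res.detail["sessions_used"] == [1, 2, 3, 4, 5]


def test_correct_error_insufficient_sessions_raises():
    spectra = [_spectrum(0, t, np.zeros(len(FREQS)), correct=True) for t in range(6)]
    with pytest.raises(InsufficientDataError):
        compare_correct_error(spectra)
    with pytest.raises(ValueError):
        compare_correct_error(spectra, grouping="task3")


def test_correct_error_recovers_theta_band_effect():
    """A 3-dB theta-band offset between correct and error trials is flagged
    in the 4-8 Hz bins and (almost) nowhere else, across seeded replicates."""
    theta_mask = (FREQS >= 4) & (FREQS <= 8)
    hits = 0
    for rep in range(50):
        rng = np.random.default_rng(1000 + rep)
        spectra = []
        for s in range(6):
            for t in range(15):
                correct = t < 10
                psd = rng.normal(0.0, 1.0, size=len(FREQS))
                if correct:
                    psd[theta_mask] -= 3.0
                spectra.append(_spectrum(s, t, psd, correct=correct))
        res = compare_correct_error(spectra)
        # the effect is detected and significance stays confined to theta bins
        ok = np.any(res.significant[theta_mask]) and not np.any(res.significant[~theta_mask])
        hits += ok
    assert hits >= 45


def test_first_final_identical_sessions_not_significant():
    rng = np.random.default_rng(49)
    trial_psds = [rng.normal(size=len(FREQS)) for _ in range(10)]
    spectra = [_spectrum(0, t, p) for t, p in enumerate(trial_psds)]
    spectra += [_spectrum(5, t, p) for t, p in enumerate(trial_psds)]
    res = compare_first_final(spectra)
    assert not np.any(res.significant)
    assert np.allclose(res.direction, 0.0)


def test_first_final_handles_unequal_trial_counts():
    rng = np.random.default_rng(50)
    spectra = [_spectrum(0, t, rng.normal(size=len(FREQS))) for t in range(20)]
    spectra += [_spectrum(5, t, rng.normal(size=len(FREQS))) for t in range(17)]
    res = compare_first_final(spectra)
    assert res.detail["n_first"] == 20
    assert res.detail["n_final"] == 17
    assert res.n_units == 37


def test_first_final_validation():
    spectra = [_spectrum(0, 0, np.zeros(len(FREQS)))]
    with pytest.raises(InsufficientDataError):
        compare_first_final(spectra)
    spectra += [_spectrum(1, 0, np.zeros(len(FREQS)))]
    with pytest.raises(ValueError):
        compare_first_final(spectra)


def test_binwise_to_frame_columns():
    rng = np.random.default_rng(51)
    spectra = [_spectrum(0, t, rng.normal(size=len(FREQS))) for t in range(5)]
    spectra += [_spectrum(1, t, rng.normal(size=len(FREQS))) for t in range(5)]
    df = binwise_to_frame(compare_first_final(spectra))
    assert list(df.columns) == ["freq", "stat", "p_raw", "p_holm", "significant", "direction"]
    assert len(df) == len(FREQS)


# ------------------------------------------------------------- correlations

def _scores(task1, recall, task2):
    return RecognitionScores(
        task1_accuracy=task1,
        task1_recall=recall,
        task2_accuracy=task2,
        n_trials=20,
        n_old=10,
        task2_denominator=8,
    )


def _correlation_inputs(thetas, accuracies):
    spectra = []
    scores = {}
    for s, (theta, acc) in enumerate(zip(thetas, accuracies)):
        for t in range(4):
            sp = _spectrum(s, t, np.zeros(len(FREQS)), correct=True, task2=(t % 2 == 0), old=True)
            sp.theta_power = theta
            spectra.append(sp)
        scores[s] = _scores(acc, acc, acc)
    return spectra, scores


def test_correlation_perfect_monotone_rho_one():
    spectra, scores = _correlation_inputs([1, 2, 3, 4, 5, 6], [50, 60, 70, 80, 90, 100])
    results = theta_behavior_correlation(spectra, scores)
    assert len(results) == 3
    for r in results:
        assert r.defined
        assert r.rho == pytest.approx(1.0)
        assert r.n == 6
    # Holm family over the three analyses
    assert all(np.isfinite(r.p_holm) for r in results)


def test_correlation_constant_score_flagged_undefined():
    spectra, scores = _correlation_inputs([1, 2, 3, 4, 5, 6], [80, 80, 80, 80, 80, 80])
    results = theta_behavior_correlation(spectra, scores)
    for r in results:
        assert not r.defined
        assert np.isnan(r.rho)
        assert np.isnan(r.p_holm)


def test_correlation_requires_four_sessions():
    spectra, scores = _correlation_inputs([1, 2, 3], [50, 60, 70])
    with pytest.raises(InsufficientDataError):
        theta_behavior_correlation(spectra, scores)


# -------------------------------------------------------- pipeline smoke

def test_epoch_fast_path_produces_trial_spectra(plans4_small):
    learner = LearnerModel(theta_gain_by_session=(1.0,) * 4)
    spectra, scores = simulate_epoch_spectra(
        plans4_small, learner, NoiseModel(), OscillationSpec(), None, seed=52
    )
    assert len(spectra) == 24
    assert sorted(scores) == [0, 1, 2, 3]
    for sp in spectra:
        assert np.isfinite(sp.log_theta)
        assert sp.k_used in (10, 6, 4)
        assert sp.psd_db.shape == sp.freqs.shape


def test_full_analysis_report_structure(plans4_small):
    learner = LearnerModel(theta_gain_by_session=(1.0, 1.0, 1.3, 1.3), base_success_prob=0.7)
    recordings = generate_experiment(
        plans4_small, learner, NoiseModel(), OscillationSpec(), None, seed=53
    )
    report = analyze(recordings, RunConfig(seed=53))
    assert report.anova.df_between == 3
    assert report.anova.df_within == 24 - 4
    assert len(report.correlations) == 3
    assert len(report.k_by_trial) == 24
    assert len(report.config_hash) == 12
    assert sorted(report.scores_by_session) == [0, 1, 2, 3]
    payload = report.to_json()
    assert '"anova"' in payload and '"first_final"' in payload
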