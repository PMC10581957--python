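# Methods

This document describes the generative model, the analysis chain, the
parameter defaults and why they were chosen, and the numerical decisions
made in the implementation. It makes no empirical claims beyond what the
code computes on synthetic data.

## Experimental design being modeled

A session opens with 20 s of rest, followed by 20 trials of 39 s each
(800 s total):

| phase     | duration | content |
|-----------|----------|---------|
| encoding  | 13 s     | five words, each a 1.0-s blank + 1.6-s display (2.6-s cycle) |
| task 1    | 8 s      | old/new judgment on a probe word |
| task 2    | 8 s      | if "old": at which position (1–5) did it appear? |
| feedback  | 10 s     | bar showing the trial's theta power |

Each trial uses one six-word set balanced for familiarity; five words are
presented, the sixth is the lure. Ten trials probe a presented word ("old"),
ten probe the held-out word ("new"). Task 2 accuracy is scored only over
old probes the participant correctly called old; when that denominator is
zero the score is undefined rather than zero.

The theta feature is the 4–8 Hz band power of the Welch PSD (1-s Hann
segments, 50% overlap, µV²/Hz on a 1 Hz grid) of the **12-s analysis
window** — the encoding period minus its first blank second — averaged over
the four contacts.

## Generative model

### Background: random-phase 1/f^β synthesis

Each channel's background is synthesized in the frequency domain with
deterministic spectral amplitudes |S(f)| ∝ f^(−β/2) and i.i.d. uniform
phases, normalized analytically (Parseval) so the RMS equals the configured
scale exactly. Defaults: β = 2, RMS = 30 µV.

Why not shaped white noise: renormalizing a shaped-Gaussian realization to
exact RMS injects a random session-level PSD offset, because the RMS of 1/f²
noise is dominated by a handful of low-frequency degrees of freedom. That
offset made across-session comparisons reject under a true null for a
generator artifact rather than a property of the statistics. With
deterministic amplitudes the long-run spectrum carries no realization-level
offset, while the time samples remain approximately Gaussian by the central
limit theorem.

### Theta rhythm

A band-limited oscillation (default 4–8 Hz: center 6 Hz, bandwidth 4 Hz,
baseline amplitude 20 µV, total power amplitude²/2) runs **tonically through
the whole session** and is identical on all channels (a common mesial
generator). During trial *t*'s encoding window its amplitude is scaled by

  gain(session) × lognormal jitter(σ = 0.1).

Two deliberate choices:

- **Tonic, not encoding-only.** ASR calibrates on the opening rest period;
  if theta existed only during encoding, the calibration would never see the
  rhythm's strong rank-1 component and would flag it in nearly every
  encoding window, destroying the very signal being fed back. Theta is an
  ongoing rhythm; only its amplitude is task-modulated.
- **Bandwidth 4 Hz, spanning the full theta band.** A much narrower band
  produces a slowly fluctuating envelope whose short-window RMS has a heavy
  right tail; an aggressive ASR cutoff (k = 4) clips those envelope peaks.
  With the band-spanning default, ASR's theta distortion on artifact-free
  data is at the 0.1% level.

### Spike artifacts

Epileptic spikes are biphasic sharp transients (derivative-of-Gaussian,
half-width 50 ms, peak 300 µV) at Poisson onsets (default 0.2 /s),
synchronous across channels with a fixed amplitude profile
(1.0, 0.8, 0.6, 0.4) emulating a focal generator near contact 1.

### Learner and behavior

Recognition success is Bernoulli with logit(p) = logit(base) +
coupling · z, where z is the standardized log theta factor of the trial.
Coupling 0 decouples behavior from theta entirely (the null configuration);
`base_success_prob` defaults to 0.9, task 2 success to 0.7.

### What the generator does not emulate

Volume conduction and channel-specific spectra, non-stationary background,
inter-spike waveform variability, eye/muscle artifacts, behavioral learning
dynamics (practice effects), and any anatomical specificity. It is a test
harness for the measurement and statistics chain, not a brain model.

## Artifact subspace reconstruction

Calibration eigendecomposes the covariance of the (filtered) rest period
into an orthonormal component basis and summarizes each component's 0.5-s
windowed RMS by median and 1.4826·MAD — robust statistics rather than a
parametric distribution fit. Cleaning slides 0.5-s windows (50% overlap)
over the epoch; in each window the data's own covariance is
eigendecomposed, components whose variance exceeds the calibration
threshold energy (μ + k·σ per calibration component, projected onto the
window's basis) are dropped, and the window is reconstructed from the
retained subspace through the calibration mixing matrix's pseudoinverse.
Windows are re-blended with Hann weights; untouched windows pass through
exactly.

The adaptive cutoff rule maps an epoch's exceedance fraction (samples
beyond channel mean ± 3 SD, pooled over channels) to k: below 1% → 10, in
the closed band 1–1.5% → 6, above 1.5% → 4. The real-time depth-montage
configuration uses fixed k = 4; the subdural configuration applies no ASR.

A note on monotonicity: "smaller k removes more" holds for the **total**
energy removed from an epoch. Per individual window it can be violated at
the 10⁻⁴ relative level, because changing the flagged set changes the
pseudoinverse re-imputation of the retained components — a second-order
effect of the reconstruction, not a bug.

## Statistics

- **Correct vs error spectra**: per session, the mean dB spectrum
  (10·log₁₀, floor 10⁻¹² µV²/Hz) of correct and of error trials; per 1 Hz
  bin (1–100 Hz) a paired t-test across sessions; sessions lacking either
  outcome are excluded, and if fewer than two sessions have task-1 errors
  the analysis falls back to task-2 grouping. Holm over bins.
- **First vs final session**: per bin, Wilcoxon rank-sum between the two
  sessions' trial dB values (robust to unequal trial counts, e.g. a session
  aborted at trial 17); Holm over bins; direction = median difference.
- **Session ANOVA**: one-way ANOVA of per-trial log₁₀ theta power across
  sessions; η² = SS_between/SS_total; Tukey–Kramer all-pairs post-hoc
  (statsmodels). 6 × 20 trials gives df (5, 114); group sizes
  20, 17, 20, 20, 20 give (4, 92).
- **Theta–behavior correlations**: three session-level Spearman
  correlations on their specific trial subsets (all trials vs task-1
  accuracy; old-probe trials vs recall; correctly-recognized-old trials vs
  task-2 accuracy), with exact permutation p-values for n ≤ 8 sessions and
  Holm over the three analyses. Undefined correlations (constant series)
  are flagged and excluded from the family.

Holm–Bonferroni and the exact-permutation Spearman p are authored and are
verified in the tests against statsmodels and brute-force enumeration.

## Validation strategy

- **Exactness checks**: sinusoid band power = A²/2, white-noise Parseval,
  background RMS and log-log PSD slope, ANOVA/Holm/Spearman against
  independent oracles.
- **Null calibration** (200 Monte-Carlo replicates, equal gains, zero
  coupling, spike-free): familywise error of each binwise family stays at
  the nominal α within Monte-Carlo tolerance, and the correlation analyses
  show |mean ρ| < 0.15 with a type-I rate near 0.05. Spikes are disabled
  here on purpose: with spikes and per-session ASR calibration, sessions
  genuinely differ through cleaning variability, so the across-session null
  would be false and its rejection rate would not measure test calibration.
- **Pattern recovery** (50 replicates, gains [1,1,1,1,1.5,1.5], spikes on):
  Tukey flags a late-over-early session pair and the first-vs-final test
  flags positive theta bins in ≥ 90% of replicates.

The Monte-Carlo suites generate encoding epochs (plus a per-session rest
calibration epoch) directly rather than full 800-s sessions. The offline
statistics consume only encoding epochs, so this is exact for the
quantities tested and keeps the runtime within minutes.

## Numerical choices

- Welch: `scipy.signal.welch`, Hann, constant detrend, density scaling;
  band power by trapezoidal integration over the 1 Hz grid.
- Filters: zero-phase (forward-backward) 4th-order Butterworth 0.5–200 Hz
  plus an IIR notch at 50 Hz (Q = 30).
- EDF: written directly (16-bit, 1-s records, symmetric physical range
  ±⌈max |x|⌉ µV), so the round-trip error is bounded by one digital step
  (range/2¹⁵); recordings are zero-padded to whole records and trimmed to
  the plan duration on read. Reading goes through MNE, which doubles as a
  format-compliance check.
- Seeds: every public entry point takes an integer seed;
  `numpy.random.SeedSequence` derives independent per-session and per-trial
  streams, so per-component signals are reproducible in isolation.

## Limitations

- Two patients' worth of design (6 sessions) gives Spearman n = 6; the
  correlations are reported with exact p-values but are underpowered by
  construction.
- The binwise across-session tests treat trials as exchangeable units
  within a session; no mixed-effects modeling.
- ASR is the windowed-reconstruction scheme described above; it is not a
  re-implementation of any specific published toolbox, and its calibration
  uses robust location/scale rather than a fitted noise distribution.
- With spike artifacts enabled, per-session ASR calibration makes sessions
  differ slightly even under equal gains; broadband bins can then reach
  significance in first-vs-final comparisons. This is a property of the
  measurement chain, visible in the worked example (bins near 73–75 Hz),
  not a theta effect.
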