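# Methods

## The decoding problem

A row/column speller presents an `n_rows × n_cols` character grid (default
5 × 6). Stimuli are the `n_rows + n_cols` row/column intensifications
(default 11), flashed once each per block in fresh random order; blocks
repeat `n_repetitions` times per attended character (default 15). Flash
onsets are spaced exactly one inter-stimulus interval apart (250 ms, flash
duration 150 ms), with a 3 s blank between characters and a 1 s lead-in so
pre-stimulus windows fit. Two stimuli per block — the attended character's
row and column — are targets. This yields the counting identities used
throughout: `n_chars × n_reps × 2` target and
`n_chars × n_reps × (n_stimuli − 2)` non-target flashes (420 and 1890 for
14 characters × 15 repetitions), verified by enumeration of built
schedules. The grid is fully configurable; character indices are 0-based
and display symbols are arbitrary strings.

## Pipeline

1. **Band-pass 1–12 Hz.** Windowed-sinc (Hamming) linear-phase FIR,
   tap count chosen for a ~1 Hz transition at the given rate (odd length,
   type I), applied in a single delay-compensated pass
   (`mode="same"` convolution) — exactly zero-phase, so P300 latencies are
   not shifted. Filtering runs on the continuous signal so edge transients
   fall between epochs. Stopband suppression (~−53 dB) removes drift and
   50 Hz line interference.
2. **Blink rejection.** FastICA decomposes the continuous recording into
   `n_channels` components; a component is zeroed before back-projection
   when its mean absolute mixing weight over the frontal electrodes
   (Fp1/Fp2) exceeds `ratio_threshold` (default 3.0) times its mean
   absolute weight elsewhere. Any decomposition providing a mixing matrix
   satisfies the contract; rank-deficient input raises an estimation error
   carrying the covariance condition number. ICA runs per recording file.
3. **Epoching.** Half-open windows `[−200, 800)` ms around each onset, so
   one epoch is exactly `round(fs × 1 s)` samples (500 at 500 Hz). Events
   whose window would be truncated are dropped, warned about, and counted.
4. **Baseline z-scoring.** Per trial and channel,
   `(x − mean_baseline)/sd_baseline` with statistics from the `[−200, 0)`
   ms segment, applied to the whole epoch so baseline and response share
   one scale. Zero baseline variance raises a degenerate-input error
   naming the trial and channel.

## Features

- **Peak picking**: max of the trial-averaged waveform inside the P300
  window (220–500 ms, inclusive ends) minus the minimum over `[0, 220)` ms.
  The pre-window minimum is taken unconstrained; a warning flags the
  (unexpected) case where it is positive. The score is invariant to
  constant offsets because both terms shift together.
- **Area**: plain sum of samples inside the P300 window (141 samples at
  500 Hz with inclusive endpoints), linear in the input.
- **Time-frequency maps**: complex Morlet
  `ψ(t) = (π f_b)^{−1/2} e^{2πi f_c t} e^{−t²/f_b}` (defaults
  `f_b = 2`, `f_c = 1`), scale-to-frequency map `f = f_c/(a·dt)`,
  coefficients on the amplitude-flat `1/a` convention so equal-amplitude
  tones score equally at every frequency. Computed per trial and averaged.
  Descriptive output only — not a classifier feature.
- **Mean PLV** and **edge count** from the connectivity stage below.

## Phase-locking value and surrogate edges

Phases come from the analytic-signal angle of each band-limited epoch.
For each of the `C(n_channels, 2)` pairs (171 at 19 channels) the PLV at
epoch time *t* is the mean resultant length of the per-trial phase
differences over the `Tr` selected trials; it is 1 exactly when the phase
relation is identical in every trial and has null expectation
`√π/(2√Tr)` (the Rayleigh resultant; `E[PLV²] = 1/Tr`) for independent
phases, so it is meaningless on a single trial. The implementation is
vectorized (batched Hermitian products); a pure-Python complex-sum oracle
in `validation.py` pins it to 1e-12.

Connectivity is decided on the 200–500 ms window average (inclusive ends),
bracketing the P300 and staying clear of Hilbert edge effects. For
significance, every trial/channel signal is independently phase-randomized
in the frequency domain (uniform spectral phase rotations, DC and Nyquist
fixed, amplitude spectrum preserved exactly) and the full
phase → PLV → window-average pipeline is re-run per surrogate (default
200). The add-one empirical rank `p = (1 + #{surr ≥ obs})/(1 + n_surr)`
avoids p = 0; an edge is kept at `p < α` (default 0.01). Randomizing only
one channel of each pair is available as an option; the default randomizes
both. Surrogates run in single precision — float32 resolution is orders of
magnitude below the `1/√Tr` spread of the null — and the analytic signal
is built directly from the randomized one-sided spectrum, which equals the
Hilbert transform of the time-domain surrogate exactly.

An optional z-scoring of PLV time courses against the pre-stimulus
baseline is provided for display, but is off on the edge-decision path:
baseline normalization is a waveform-level convention, and rank tests
against surrogates are invariant to monotone rescaling only when applied
consistently, so the raw window average is the cleaner decision surface.

Condition contrasts (edge counts or mean PLV, target vs non-target) use
the two-sided Wilcoxon rank-sum test. When per-character edge counts are
contrasted, non-target graphs are computed on 30-trial subsets matched to
the 30 target trials: the PLV null level depends on `Tr`, and unequal
trial counts would confound the comparison.

## Decoding

Observations are stimulus trial sets — the pooled trials of one
row/column stimulus for one attended character (11 sets per character).
Decoding uses a linear SVM with class-weighted loss (targets and
non-targets are 2:9 imbalanced) on standardized features; evaluation
splits *by character* (default 80/20, 10 repeats), so all sets of a test
character are unseen during training; accuracy comes from the signed
decision and AUC from the decision function. Character prediction is
classifier-free: the row and the column whose graphs carry the most
significant edges intersect at the predicted character, with ties broken
by higher mean PLV and then lowest stimulus id (and recorded). The
`auc_vs_trials` evaluation re-draws random `k`-subsets of every set's
trials per repeat and rejects `k < 2` whenever a PLV feature is requested.
xDAWN and SWLDA exist only as named pluggable-baseline slots; the bundled
baselines are the feature sets defined here.

## Synthetic sessions

The generator emulates the statistical structure the pipeline exploits,
not biophysics:

- **Background noise**: per-channel Gaussian noise, white or 1/f
  (default), scaled to `noise_sd` (8 µV default). 1/f makes the band-pass
  stage consequential.
- **Evoked response**: on target flashes, the ERP channels receive a
  positive Gaussian deflection (amplitude 8 µV, peak 350 ms, width 55 ms)
  preceded by a smaller negativity near 150 ms — so peak picking's
  min-before/max-in-window structure is exercised. The injected template
  is returned as ground truth.
- **Phase coupling**: each connected component of the configured coupling
  graph owns a hidden phase process — a carrier drawn uniformly from
  `carrier_band` (4–8 Hz default) plus a slow random-walk drift — and each
  member channel observes it with an independent Gaussian offset of
  standard deviation `phase_jitter_sd`, giving the tractable coupling
  expectation `exp(−phase_jitter_sd²)` used in validation. Ground-truth
  edges equal the configured pairs, exact when components are cliques (the
  presets' are). On *non-target* flashes the same channels carry
  oscillations of the same amplitude and band but with fully independent
  phases, so conditions differ in phase consistency, not spectral content.
- **Oscillation timing**: the coupled oscillation spans 150–550 ms
  post-onset, a transient around the P300. Because the 250 ms ISI makes
  1 s epochs overlap, evoked structure necessarily bleeds between
  neighboring epochs — a property of the real paradigm as well; the
  transient window keeps that bleed to ~1/6 of a neighbor's analysis
  window. Injection-alignment tests use wide-ISI schedules to isolate
  single flashes.

What the generator does *not* model: volume conduction and realistic
forward mixing, non-stationary artifacts (blinks are simulated only in the
dedicated ICA tests, with explicit mixing matrices), latency jitter of the
evoked response, and inter-subject variability. Passing tests therefore
demonstrate correctness of the *method* under its stated assumptions, not
expected performance on clinical recordings.

Presets: `"reference"` (19 channels at 500 Hz, 14 characters × 15
repetitions, a parieto-occipital coupling clique plus O1–O2, jitter
0.25 rad) mirrors the reference acquisition scale; `"tiny"` (4 channels,
250 Hz) runs the full pipeline in seconds.

## Validation scenarios and problem sizes

Structural identities (counting, pair counts, epoch lengths) run at the
full 19-channel / 500 Hz scale. Stochastic scenarios choose sizes where
the tested statistics are unchanged but repetition is affordable on one
core:

- **Null calibration**: 12 independent no-coupling sessions × 171 pairs =
  2052 tests at α = 0.01 with 200 surrogates, checked against the binomial
  95% interval. The background here is white: the rank test's null assumes
  independent trials, and the 1/f default's multi-second autocorrelation
  at the 1 Hz band edge makes trials weakly dependent, which measurably
  (and genuinely) inflates the false-positive rate by a few tenths of a
  percentage point — a caveat that applies to real EEG too and is the
  reason matched, surrogate-based thresholds rather than fixed PLV cutoffs
  are used in the first place.
- **Edge recovery**: 20 sessions at jitter 0.3 rad, `Tr = 30` (the
  per-character target trial count), 7 true edges; median sensitivity and
  false-positive rate against ground truth. Note the evoked template
  itself phase-locks the ERP channels — real evoked synchrony, counted as
  true edges when it coincides with the coupling clique.
- **Decoding scenarios** (spelling accuracy, AUC vs trial count): 14
  characters × 15 repetitions at 8 channels / 100 Hz — phase statistics
  depend on trial counts and the 1–12 Hz band (well below the 50 Hz
  Nyquist), not on montage density or sampling rate. Spelling uses strong
  coupling (jitter 0.25); the AUC curve uses moderate coupling (jitter
  0.9) so performance is unsaturated and its rise with trial count is
  visible; medians pool 20 split-repeats over 2 sessions per count.
- **Condition contrast**: the full `"reference"` fixture; per-character
  edge counts, non-target graphs on size-matched 30-trial subsets.

## Numerical choices

- FIR taps `ceil(3.3 fs / transition)`, forced odd; single-pass
  delay-compensated application (idempotent to ≥ 0.999 correlation on
  in-band input).
- Epoch windows half-open, feature windows inclusive; sample counts
  documented so sums are bit-reproducible.
- PLV pairs enumerated `i < j` in upper-triangle order everywhere;
  weight matrices symmetric with zero diagonal.
- Surrogate p-values use the add-one rank convention; `n_surrogates ≥
  1/α − 1` is enforced.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); fixtures are bit-reproducible.
- Degenerate inputs fail loudly: all-zero signals (undefined phase), zero
  baseline variance, single-trial PLV, single-class tables.

## Known limitations

- Scalp-level PLV is susceptible to volume conduction; zero-lag spread is
  neither modeled nor corrected (no phase-lag-index variant).
- The surrogate test is mildly anticonservative when background noise is
  temporally dependent across trials (see null calibration above).
- PLV features require multiple trials per stimulus by construction;
  single-trial decoding is out of scope.
- EDF export is 16-bit with per-channel symmetric scaling; quantization
  error is bounded by half a digital step (~1.5e-5 of the channel range).
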