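# Methods

`erppls` implements a complete, testable analysis chain for three-condition
audiovisual congruency ERP experiments in two groups of children: synthetic
data generation with known ground truth, EEG preprocessing, per-subject ERP
averaging with N400/P600 feature extraction, and task Partial Least Squares
(PLS) with permutation inference, orchestrated into two 24-analysis
batteries.

## The statistical model

Both PLS variants operate on the matrix of design-cell mean feature
vectors.  For a design with k cells and p = 150 features (the component
window samples), let M be the k x p matrix whose row j is the mean feature
vector of cell j, and let M_c = M − 1·m̄ᵀ be its grand-mean-centered form
(column means across cells removed).

- **Mean-centered PLS** computes the SVD M_c = U S Vᵀ.  The columns of U
  are *design saliences* — data-driven contrasts across the cells — and the
  columns of V are the corresponding feature saliences.  The tested
  statistic is the first singular value s₁, summarizing how strongly the
  cells differ across all 150 features at once.  Only the first latent
  variable is tested: the analysis reports a single p-value per design.
- **Contrast PLS** projects the centered cell means onto an a-priori unit
  contrast c: the feature salience is M_cᵀc and the statistic its Euclidean
  norm.  For k = 2 with c = (1, −1)/√2 this equals the mean-centered first
  singular value exactly (asserted in the tests).

**Permutation inference.**  Group comparisons assume exchangeability of
subjects between groups: group labels are permuted across subjects, with
all of a subject's condition rows moving together.  Condition comparisons
are repeated measures on the same subjects, so condition labels are
permuted within each subject.  The p-value uses the add-one estimator
p = (1 + #{s* ≥ s}) / (1 + B), which can never be exactly zero.  The mode
is explicit in every result and report.  Testing one contrast across all
features at once is what sidesteps per-timepoint multiple comparisons; no
correction is applied across the separate analyses of a battery by
default (a Benjamini–Hochberg option exists and the report states which
mode ran).

**Batteries.**  The condition battery runs mean-centered PLS over the
three conditions separately per group, ERP component and electrode
(2 x 2 x 6 = 24 analyses, 3 cells each, within-subject permutations).  The
group battery runs contrast PLS per condition set, component and electrode
(2 x 2 x 6 = 24 analyses, between-subject permutations): the congruent
analyses compare the two groups (2 cells, contrast (1, −1)/√2) and the
incongruent analyses use 4 cells ordered (ASD-semantic, ASD-pragmatic,
TD-semantic, TD-pragmatic).  Two incongruent contrast presets ship:
the published vector `[1, 1, −1, 1]` (the default) and the sign-symmetric
`[1, 1, −1, −1]`, which is its plausible intended form; the choice is
config-driven, not hard-coded, because the printed vector's asymmetry looks
like a typographical slip but cannot be verified.  The congruent-condition
contrast is likewise configurable, defaulting to (1, −1).

## Preprocessing

Fixed order: 1–25 Hz band-pass of the EEG leads → optional per-subject
channel-drop list → ocular-artifact regression → linear detrend → epoching
to the half-open [−200, 800) ms window (500 samples at 500 Hz) → baseline
correction over [−200, 0) ms → amplitude rejection → correct-response
selection.

- **Filter realization**: 4th-order Butterworth applied forward–backward
  (`scipy.signal.sosfiltfilt`), i.e. zero phase, so component latencies are
  not shifted.  Order and realization are configuration defaults, not
  claims about the original recordings.
- **Ocular regression**: the two EOG channels are band-passed 1–7 Hz and
  jointly regressed (with an intercept) out of every EEG channel on the
  continuous signal; the residual is exactly uncorrelated with the
  regressors and never has larger variance than the input.  A zero-variance
  regressor is skipped with a warning.  Epoch-wise regression would be
  unstable on 500-sample epochs, which is why the regression is continuous.
- **Amplitude rejection** takes the *median* of the signed sample values
  per EEG channel within each epoch and flags the trial if any channel's
  median falls outside ±150 μV — the literal reading of the rule; a
  peak-to-peak mode is available as a config option.  EOG channels are not
  tested (they act only as regressors).
- **Subject inclusion** is strict, as worded: more than 20 correct trials,
  fewer than 60 incorrect-or-missed trials, IQ at least 70.  Every failed
  criterion is reported.
- **Windows** are half-open, [200, 500) ms for N400 and [500, 800) ms for
  P600: at 500 Hz each holds exactly 150 samples and the two share no
  boundary sample — the stated feature count forces this convention.

## The synthetic-data generator

The generator emulates the study regime end to end so that every stage is
testable without any recording being available.  Per subject,

    EEG(t) = ERP template + 1/f background noise + mixed blink process
    EOG(t) = blink process + small pink measurement noise

- **ERP components** are Gaussian bumps (the component literature fixes
  windows, not waveform shapes): N400 centered at 400 ms (SD 60 ms,
  negative, centro-parietal topography) and P600 at 650 ms (SD 80 ms,
  positive, centro-parietal).  Planted amplitudes vary by group x
  condition and mirror the qualitative published pattern: a 2 μV P600
  congruency effect present only in the TD-like group, group differences on
  the incongruent N400 and on P600.  Because the two Gaussians overlap in
  time, windows are not perfectly component-pure — a realistic property
  real ERPs share.
- **Background noise** is 1/f-power (pink) Gaussian noise, synthesized in
  the frequency domain and scaled to 10 μV RMS per channel; pink rather
  than white because EEG spectra are 1/f-like and a low-frequency-heavy
  background genuinely exercises the band-pass and detrending stages.  EOG
  channels carry 5 μV pink noise.
- **Blinks** are positive 300 ms raised-cosine pulses (standard blink
  morphology), Poisson-arriving at 0.15 /s with 150 μV amplitude at the
  first EOG lead (0.8 of that at the second, so the two regressors are
  correlated but not collinear), mixed into the EEG with frontal-weighted
  coefficients (Fz 0.15 down to Pz 0.02) so that pre-cleaning blink
  variance orders Fz > Pz.
- **Behavior**: responses are Bernoulli-correct at 0.8 (non-correct trials
  split 3:1 into incorrect and missed); reaction times are log-normal with
  μ = 0.425, σ = 0.30 (mean ≈ 1.6 s, matching the 1.5–1.8 s range), defined
  from the end of the second spoken word, which the generator treats as the
  reference point without modeling audio duration.
- **Cohort**: 15 + 37 subjects; per-subject gain ~ N(1, 0.2) (truncated at
  0.2) scales all component amplitudes, modeling between-subject amplitude
  variability that cancels in within-subject condition comparisons;
  synthetic IQ ~ N(95.7, 21) for the ASD-like and N(109.6, 13.7) for the
  TD-like group, truncated to [40, 160], so the IQ < 70 exclusion rule is
  exercised.
- **Trials**: 85 per condition by default.  The published per-condition
  trial counts (~100–115) combined with 80% accuracy would put the expected
  number of incorrect/missed trials at or above the 60-trial exclusion
  threshold, excluding about half of a simulated cohort; 85 trials per
  condition (255 total, ~51 expected bad trials) keeps the cohort almost
  fully includable while preserving the one-third-per-condition structure,
  the accuracy regime, and comfortably more than 60 retained trials per
  condition.  Occasional excluded subjects remain — as in the study the
  paradigm models, where exclusions were substantial.
- **Timing**: the inter-trial interval is a free parameter (the paradigm's
  is not published); the default is 2.5 s, and the enforced lower bound is
  the epoch length plus a 1 s response window.

What the generator does *not* emulate: real scalp topography beyond scalar
channel gains, non-stationary noise, muscle or line artifacts, saccades
(blinks only), latency jitter of components, or any relation between IQ and
the EEG.  Passing tests therefore demonstrate correctness of the pipeline's
algorithms under a plausible signal model, not clinical validity on real
recordings.

## Monte-Carlo engines and problem sizes

Calibration (type-I error) and power experiments run hundreds of complete
studies.  Three execution paths exist, in increasing speed:

1. the per-subject reference pipeline (`generate_subject` /
   `preprocess_subject`) — the canonical implementation;
2. an **exact batched engine** (`montecarlo.preprocess_batched`) that
   performs the identical operations vectorized across subjects; stacking
   per-subject recordings and preprocessing them batched reproduces the
   reference ERPs to ~1e-13 μV (asserted in the tests);
3. a **fused engine** (`montecarlo.simulate_processed_study`) for repeated
   simulation: because generation and the continuous preprocessing stages
   are linear, the pink-noise spectrum is multiplied by the squared
   magnitude response of the zero-phase band-pass at synthesis time, blink
   pulses are scattered as pre-filtered kernels (4 s ring-down support),
   and the filtered ERP template is added at the epoch level together with
   the leakage tails of the two neighboring trials.  Validation against the
   exact engine shows agreement to ~5e-5 μV for the template path and
   ~0.06 μV for blink residuals near recording edges — two to four orders
   below the planted 2 μV effects, and condition-independent.  Noise above
   twice the band-pass edge is not synthesized (it cannot survive the
   filter), and noise scaling uses the analytic process RMS.

Simulation studies in the test suite use deliberately scaled problem
sizes, chosen a priori as the smallest regimes that still realize the
study's conditions: the power study keeps the full 15/37 cohort and ≥ 60
expected retained trials per condition (80 generated per condition) but
restricts the montage to the three analyzed centro-parietal electrodes,
uses a 2.0 s inter-trial interval, single-precision arrays and 200
permutations per test over 200 replicate studies; the type-I study uses
500 null feature matrices at the 15/37 design with 200 permutations.

## Numerical choices

- Singular vectors have an arbitrary sign; each design salience is flipped
  so its largest-magnitude element is positive (feature saliences follow),
  making outputs reproducible across LAPACK builds.
- The permutation p-value uses the add-one correction (never exactly 0).
- A degenerate all-zero centered cell-mean matrix yields p = 1 with a
  logged warning rather than an error.
- Per-analysis permutation seeds derive from the master seed and the
  analysis index through `numpy` seed sequences, so any single analysis can
  be re-run in isolation and battery results do not depend on execution
  order.
- Mean-centering leaves one exact null direction in cell space; tests
  compare singular values to a brute-force eigendecomposition oracle only
  above the rank-noise floor.
- Epoch windows, baselines and component windows are half-open throughout.
- Significance flagging in reports uses strictly p < α at α = 0.05.

## Storage

Study bundles persist as one HDF5 container of continuous recordings
(channels x time per subject, with channel labels and roles as attributes)
plus per-subject tab-separated event tables (`onset_sample`, `condition`,
`response`, `rt_seconds`, with `n/a` for missing reaction times), a
`participants.tsv` metadata table, and the ground truth as a plain-text
`key = value` file.  Epoch sets persist to HDF5 with named (trial, channel,
time) dimensions and both rejection masks.  Battery results are written as
a long-format TSV (one row per analysis), a wide per-electrode p-value
table with significance marks, and a JSON sidecar carrying the seed,
configuration hash and correction mode.

## Known limitations

- The generator's effect topographies are scalar gains; no volume
  conduction or reference effects are modeled.
- The fused engine's blink residual approximation (~0.06 μV near edges) is
  negligible for the shipped experiments but the exact engine should be
  preferred when studying the artifact-cleaning stage itself.
- The group-battery contrast defaults follow the printed analysis exactly,
  including the asymmetric incongruent vector; scientific users will likely
  prefer the symmetric preset.
- RT is generated relative to the (unmodeled) end of the second word; the
  behavioral summary reports it as given.
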