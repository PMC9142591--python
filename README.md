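# erppls

Synthetic ERP studies, EEG preprocessing, and task-PLS permutation
statistics for N400/P600 congruency experiments.

## What this is for

Event-related potential (ERP) studies of contextual-language processing
compare two groups of children — autistic (ASD) and typically developing
(TD) — on a three-condition task: a spoken two-word description either
matches a picture (*congruent*) or violates it semantically or
pragmatically (*incongruent-semantic*, *incongruent-pragmatic*).  The
dependent measures are two ERP components: the **N400** (a negativity near
400 ms, analysis window [200, 500) ms) and the **P600** (a positivity,
window [500, 800) ms), each sampled at 500 Hz so a window holds exactly
150 amplitude features.

`erppls` packages that entire analysis as a tested, reusable library:

- **`erppls.simulate`** — complete synthetic studies with known ground
  truth: 6 EEG + 2 EOG channels at 500 Hz, Gaussian-bump ERP components
  with group x condition amplitudes, 1/f background noise, raised-cosine
  blink artifacts, Bernoulli accuracy and log-normal reaction times, a
  15/37-subject cohort with synthetic IQ.
- **`erppls.preprocess`** — the fixed chain: 1–25 Hz zero-phase band-pass,
  regression of the 1–7 Hz-filtered EOG out of every EEG channel, linear
  detrend, epoching to [−200, 800) ms, baseline correction over
  [−200, 0) ms, ±150 μV median-amplitude trial rejection, correct-response
  selection, and the strict subject-inclusion rule (> 20 correct, < 60
  incorrect/missed, IQ ≥ 70).
- **`erppls.features`** — per-subject condition ERPs, 150-sample component
  windows, subjects-within-cells feature matrices, behavioral summaries.
- **`erppls.pls`** — the statistics.  For a design with k cells, the k x 150
  matrix of cell-mean features is grand-mean-centered to M_c.
  *Mean-centered PLS* decomposes M_c = U S Vᵀ and tests the first singular
  value; the matching column of U is the data-driven contrast across cells.
  *Contrast PLS* tests ‖M_cᵀc‖ for an a-priori unit contrast c.  Either way
  significance comes from a permutation test (between-subject for group
  comparisons, within-subject for condition comparisons) with the add-one
  p-value p = (1 + #{s\* ≥ s})/(1 + B), B = 1000 by default — one p-value
  per contrast for all features at once.
- **`erppls.pipeline`** — the two standard batteries (24 mean-centered
  condition analyses and 24 contrast group analyses: 2 x 2 components x 6
  electrodes each) and the wide per-electrode report.
- **`erppls.montecarlo`** — vectorized engines for power/type-I studies
  that run hundreds of complete simulated studies in minutes.

## A worked example

```python
from dataclasses import replace
import erppls

truth = replace(erppls.default_ground_truth(),
                n_subjects_per_group=(8, 12), n_trials_per_condition=50)
study = erppls.generate_study(truth, seed=11)
results, processed = erppls.run_study(study, seed=12, n_perm=200)
print(erppls.report_table(results, alpha=0.05).to_string(index=False))
```

prints (abridged; `*` marks p < 0.05):

```
component            comparison     F7     Fz    F8     Cz    CP5     Pz
     N400  TD across conditions 0.020* 0.015* 0.289 0.005* 0.005* 0.010*
     P600 ASD across conditions  0.617  0.697 0.866  0.303  0.861  0.512
     P600  TD across conditions 0.020* 0.005* 0.104 0.005* 0.005* 0.005*
     ...
```

Each cell is one permutation p-value for the overall contrast of that
analysis.  The planted ground truth gives the TD-like group a 2 μV P600
congruency effect and leaves the ASD-like group without one — so the TD
condition rows light up at the centro-parietal electrodes while the ASD
rows stay at chance, and the group comparisons pick up the built-in
between-group amplitude differences.

The `examples/` directory holds one short script per capability
(simulation, preprocessing + ERPs, PLS on a feature matrix, the full
batteries); each prints what it computes and says what the numbers mean.
A thin CLI mirrors the stages: `erppls simulate`, `erppls preprocess`,
`erppls analyze`, `erppls report`.

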