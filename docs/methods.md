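# Methods

This note defines the statistical model behind every public function, fixes
all parameters with units and defaults, and records the numerical choices and
their rationale. It is the reference the tests are written against.

## 1. Data model

The unit of analysis is the **gamma power trace (GPT)** of one depth-electrode
contact: a `[trials x 333]` matrix of baseline-corrected gamma-band power in
dB, on the time axis `t_k = -0.3 + k / 256` s, `k = 0..332` (i.e. `[-0.3, 1)` s
sampled at 256 Hz). Each trial carries a condition label, `angry` or `happy`;
`angry` is the positive class throughout. Contacts carry an anatomical label —
a (Desikan–Killiany structure name, hemisphere) pair; hemispheres are never
merged at any stage of aggregation.

## 2. Spectral chain (`ieegcontrast.spectral`)

Raw multichannel voltage is turned into GPTs by, in order:

1. **Notch filter** — zero-phase Hamming-window FIR at 50, 100 and 150 Hz,
   width 2 Hz per notch.
2. **Common average reference** — subtract the instantaneous mean of the good
   channels from every channel; at least 2 good channels required.
3. **Epoching** — windows of `[-0.3, 1]` s around stimulus onset, padded by a
   1 s buffer on each side (total `[-1.3, 2]` s) to absorb wavelet edge
   artifacts; onsets too close to a recording edge are dropped with a warning.
4. **Resampling** — polyphase resampling to 256 Hz (845 samples per buffered
   epoch).
5. **Morlet decomposition** — wavelet power at 1, 2, …, 125 Hz with
   `n_cycles(f) = min(max(3, f/2), 2f)` cycles, then cropped to `[-0.3, 1)` s.
6. **Baseline correction** — `10·log10(P / mean P in [-0.3, 0] s)`, per trial,
   channel and frequency. A non-positive baseline mean is an error.
7. **Gamma averaging** — mean over the 61 frequency rows in 55–115 Hz
   (inclusive).

**Numerical choice — the `2f` cap on `n_cycles`.** The plain rule
`max(3, f/2)` gives a 3-cycle wavelet at 1 Hz, which at 5 SDs is ≈ 4.8 s long —
longer than the 3.3 s buffered epoch, so the transform is undefined there. The
cap `2f` binds only below 1.5 Hz and leaves every frequency at or above 2 Hz,
in particular the entire gamma band, unchanged.

## 3. Cluster-level permutation test (`ieegcontrast.permcluster`)

Two-sample test on `[trials x time]` matrices `A` (nA trials) and `B` (nB
trials):

* **Pointwise statistic** — pooled-variance two-sample t at each timepoint.
* **Cluster forming** — contiguous runs of `|t| > t_crit` with
  `t_crit = t⁻¹(1 − p/2, nA + nB − 2)`, `p = 0.05`, separately per sign of t.
* **Cluster mass** — sum of t over the run.
* **Null distribution** — for each of `n_permutations = 1000` random
  relabelings of the pooled trials, the maximum **absolute** cluster mass
  (0 when no cluster forms).
* **p-value** — `(1 + #{null ≥ |observed mass|}) / (1 + n_permutations)`; a
  cluster is significant at `cluster_alpha = 0.05`.

Pooled rows are canonicalized (lexicographic sort) before drawing the null, so
p-values are invariant to trial order. The per-structure variant vertically
stacks the trials of all contacts sharing one (structure, hemisphere) before
testing.

Note on cross-checking: `mne.stats.permutation_cluster_test` forms identical
clusters but its two-tailed null records the maximum *signed* cluster sum
rather than the maximum absolute mass, so only the dominant cluster's p-value
is directly comparable between the two implementations. The test suite checks
cluster geometry exactly and the dominant p within 0.01, plus an
exhaustive-relabeling oracle on small inputs.

## 4. Per-contact decoding (`ieegcontrast.mlcontrast`)

* **Features** — per trial, 5 statistics (mean, SD with `ddof=1`, median,
  skewness, excess kurtosis; the standardized-moment estimators, defined as 0
  on zero-variance intervals) over 3 latency intervals `[0.2, 0.4)`,
  `[0.4, 0.6)`, `[0.6, 1.0]` s → 15 features, interval-major order.
* **Augmentation** — inside each training fold only: every training trial
  contributes two extra series, itself minus the angry-mean trace and itself
  minus the happy-mean trace (means over training trials), keeping its label;
  3n training series total. Test folds contain original trials only.
* **Classifier** — random forest, Gini criterion, with hyperparameters from
  the space `n_estimators ∈ {250, 500, 1000}`, `max_depth ∈ {2..10}`,
  `max_features ∈ {0.15, 0.5, 0.75}` (81 points). The space is searched
  **exhaustively by grid** — deterministic, and smaller than the ~100
  iterations a model-based optimizer would spend on it. Selection uses one
  shared 10-fold stratified CV; the reported score comes from a fresh,
  differently seeded CV with the winning parameters.
* **Score** — normalized Matthews correlation coefficient,
  `NMCC = (MCC + 1)/2`, chance 0.5; MCC is the standard formula
  `(TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN))`, defined as 0 when any
  denominator factor is 0 (degenerate single-class predictions).
* **Significance** — two-sided one-sample t-test of the 10 fold NMCCs against
  0.5 at α = 0.05, requiring the mean above 0.5.

**Calibration configuration.** Null calibration (and the packaged acceptance
script) scores the pipeline with the fixed parameters
`n_estimators = 250, max_depth = 5, max_features = 0.5` and no grid search:
the chance level of the pipeline does not depend on the grid point, and the
fixed configuration makes a 200-contact calibration run tractable on one CPU.
Measured on ≥ 200 independent null contacts (60 trials per condition), the
mean CV NMCC sits at 0.5 within ±0.03.

## 5. Searchlight MVPA (`ieegcontrast.searchlight`)

Every contact is in turn the center of a **closed ball of radius 25 mm**;
all contacts of the same subject inside the ball are members (the center is
always a member of its own neighborhood). Per trial, the members' full GPT
time courses are concatenated (`members × 333` features), standardized per
feature with statistics fit on the training folds, and classified with an
L2-regularized logistic regression (`C = 1`). Scoring and the significance
rule are identical to the per-contact decoder (10-fold NMCC, t-test vs 0.5,
mean above chance). A significant searchlight is attributed to the anatomical
structure of its **center** contact. Per-center seeds are spawned
deterministically from one root seed, so parallel and serial runs are
bit-identical.

## 6. Group aggregation (`ieegcontrast.groupcompare`)

A structure is significant for a method when it contains ≥ 1 significant
contact (per-contact methods) or its pooled test is significant (permutation
method). Method agreement is the Jaccard index `|A ∩ B| / |A ∪ B|` between
two methods' significant-structure sets, computed per hemisphere; two empty
sets agree vacuously (1.0). Reported 2-decimal values use decimal
round-half-up. Reaction times are compared with two-sided Mann–Whitney U
tests, per subject and pooled; group-level means are means of per-subject
means.

### Packaged cohort summary and known discrepancies

The package ships a cohort summary fixture (per-structure implanted and
significant contact counts for the three methods, 13 subjects, 1004 implanted
contacts) and a per-subject behavioral table. Recomputing the pairwise
agreement from the structure sets in the summary reproduces the reported
ML–MVPA Jaccards (0.65 LH, 0.62 RH) and permutation–ML RH (0.52) exactly.
Three values do **not** reproduce from the fixture and are recorded here
rather than targeted:

| pair | hemisphere | recomputed | reported |
|---|---|---|---|
| permutation–ML | LH | 0.35 | 0.33 |
| permutation–MVPA | LH | 0.38 | 0.44 |
| permutation–MVPA | RH | 0.44 | 0.37 |

The permutation–MVPA pair is consistent with the two hemispheres having been
swapped in the report; the permutation–ML LH difference is a small rounding or
set-membership discrepancy that cannot be resolved from the published counts
alone. The tests pin the recomputed values.

## 7. Synthetic cohorts (`ieegcontrast.synthdata`)

* **Geometry** — per subject (default 13), 8–14 electrodes, each a straight
  line of 8–18 contacts at 3.5 mm spacing through a randomly chosen structure
  centroid with random orientation; implants are left-only / right-only /
  bilateral with probabilities 0.55 / 0.15 / 0.30. Contacts are labeled by the
  nearest same-hemisphere centroid; a rasterized label volume (2 mm voxels,
  `unknown` beyond 25 mm from every centroid) applies the same rule on a grid.
  The packaged centroid table is a hand-constructed, approximate,
  template-space stand-in (33 structures × 2 hemispheres), adequate for
  laying out trajectories, not an atlas.
* **GPT noise** — Gaussian noise smoothed by a ~50 ms moving average (13
  samples at 256 Hz) and rescaled to SD `noise_sd` (default 1), mimicking the
  temporal autocorrelation of gamma power. It carries no cross-trial or
  cross-channel structure, no artifacts and no oscillatory background: it
  exercises the statistics, not the electrophysiology.
* **Effects** — `effect_size × noise_sd` added to the angry trials of all
  contacts in the target structures, inside the effect window (default
  `[0.3, 0.6]` s); alternatively a latency-shifted Gaussian activation bump.
* **Behavior** — 45–65 trials per condition per subject; reaction times
  normal with means 0.97 s (angry) / 0.85 s (happy), SD 0.15 s, truncated
  positive.
* **Raw voltage** — per channel, 1/f-shaped (pink) noise plus a 50 Hz line
  component at 4096 Hz (configurable); target-structure channels get a
  Hann-tapered 55–115 Hz band-limited burst inside the effect window on angry
  trials. This generator exists to exercise the full spectral chain end to
  end.

## 8. Seeding and reproducibility

All randomness flows from `numpy.random.SeedSequence`: child seeds are drawn
with `generate_state` and reduced modulo 2³¹ before being handed to
scikit-learn (which requires seeds below 2³¹). Same root seed ⇒ bit-identical
results, including under searchlight parallelism. Every CLI run writes a
manifest with the seed and a hash of the configuration.

## 9. Problem sizes in the test suite

The statistical property tests choose their own problem sizes to fit a
single-CPU budget: type-I error is estimated over 500 null simulations of
15 + 15 trials × 60 timepoints with 500 permutations each (accepted band
[0.03, 0.08]); decoder null calibration uses 40 (forest) / 100 (logistic)
null contacts; monotonicity of decoding in effect size is checked at levels
inside each decoder's dynamic range (they saturate near-perfect above ~0.5
and ~0.75 noise SDs respectively); searchlight recovery of a 3-SD planted
effect is required in ≥ 9 of 10 seeded cohorts. The acceptance script
(`scripts/acceptance.py`) runs the full per-contact pipeline on 200 null
contacts with 60 trials per condition.
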