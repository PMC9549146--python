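# ieegcontrast

Three complementary ways of locating task-condition contrasts in intracranial
EEG gamma power — cluster-level permutation testing, per-contact
machine-learning decoding, and searchlight MVPA — plus the machinery to
compare what they find.

## The problem

Stereo-EEG depth electrodes sample the brain sparsely: a cohort of 13
patients might contribute ~1000 contacts scattered over dozens of brain
structures, with 45–65 artifact-free trials per condition each. Given
per-contact **gamma power traces** (55–115 Hz power, baseline-corrected dB,
`[-0.3, 1)` s around stimulus onset at 256 Hz), where does the brain respond
differently to two conditions (here: angry vs happy face stimuli)? The three
method families answer at different granularity:

* **Permutation cluster test** (`permcluster`) — mass-univariate: pointwise
  t-statistics, contiguous supra-threshold clusters, max-|mass| permutation
  null. Run per contact or pooled over all contacts of a (structure,
  hemisphere).
* **Per-contact decoding** (`mlcontrast`) — 15 interval statistics per trial,
  condition-mean-subtraction augmentation, random forest, 10-fold
  cross-validated NMCC (normalized Matthews correlation; chance = 0.5) tested
  against chance.
* **Searchlight MVPA** (`searchlight`) — 25 mm neighborhoods over the sparse
  3D contact cloud, full time courses standardized and concatenated, logistic
  regression decoder, the same NMCC-vs-chance rule, attributed to the
  center's structure.

`groupcompare` turns each method's output into significant-structure sets per
hemisphere and measures pairwise agreement with the Jaccard index.
`spectral` produces the gamma power traces from raw voltage; `synthdata`
generates cohorts with known planted effects so every method can be validated
against ground truth; `geometry` handles contact labeling and neighborhoods;
`io` the file formats; `cli` a thin command-line pipeline.

## Worked example

Simulate a 4-subject cohort with a 1.5-SD effect planted in its best-covered
structure, then test every structure pool:

```bash
python examples/01_simulate_cohort.py
python examples/02_permutation_clusters.py
```

The first command prints

```
cohort: 118 contacts across 4 subjects -> scratch/example_cohort
planted effect: 1.5 SD on [('lingual', 'LH')] (26 contacts), window (0.3, 0.6) s
```

and the second finds exactly that structure, at exactly that latency window:

```
structure                    hemi   n  clusters (window s, p)
...
lingual                      LH    26  [+0.30,+0.60] p=0.001*; [+0.81,+0.83] p=0.616 ; ...
...
```

The same cohort can be pushed through the other two methods and the agreement
summary (`examples/03_contact_decoding.py`,
`examples/04_searchlight_and_agreement.py` — the decoding examples take a few
minutes), and `examples/05_spectral_pipeline.py` runs the full raw-voltage →
gamma-trace chain on a simulated recording with an embedded gamma burst.

Equivalent shell pipeline:

```bash
ieegcontrast simulate --out-dir scratch/run --seed 1 --subjects 4 \
    --effect-size 1.5 --target fusiform:LH
ieegcontrast permtest    --gpts scratch/run/gpts.npz --out scratch/run/perm.tsv
ieegcontrast ml          --gpts scratch/run/gpts.npz --out scratch/run/ml.tsv
ieegcontrast searchlight --gpts scratch/run/gpts.npz \
    --electrodes scratch/run/electrodes.tsv --out scratch/run/mvpa.tsv
ieegcontrast compare --perm scratch/run/perm.tsv --ml scratch/run/ml.tsv \
    --mvpa scratch/run/mvpa.tsv --out-dir scratch/run/agreement
```

## Layout

```
src/ieegcontrast/    library (geometry, spectral, permcluster, mlcontrast,
                     searchlight, groupcompare, synthdata, io, cli, data/)
tests/               pytest suite, including the acceptance criteria
scripts/acceptance.py  null-calibration acceptance run
examples/            narrative analysis scripts (01-05)
docs/methods.md      model, parameters, numerical choices, known discrepancies
```

All randomness is seeded through `numpy.random.SeedSequence`; identical seeds
give bit-identical results, including under parallel searchlight execution.
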