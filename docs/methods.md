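# Methods

This document specifies the statistical model implemented by `mvpa_adapt`:
what the synthetic-data generator produces, how time series are turned into
decoding samples, how the searchlight decoders are defined, and how
group-level significance is assigned. It also records the numerical choices
and the known limitations of the emulated method.

## Study design being emulated

The package emulates a developmental fMRI-adaptation study of numerosity
coding. Children of two age groups (labelled `5yo` and `8yo`) view blocks of
stimuli in up to three formats — dot arrays (`dots`), Arabic digits
(`digits`) and letters (`letters`) — under two conditions:

- **adaptation**: the task-relevant property repeats within the block,
- **no-adaptation**: the property varies within the block.

Voxels whose multivoxel activity pattern distinguishes the two conditions are
taken to carry information about the adapted property. The headline analyses
are *cross-participant*: classifiers are trained on some participants'
patterns and tested on held-out participants, so above-chance accuracy
implies spatially consistent coding across brains. Between-format transfer
(train on dots, test on digits, and vice versa) operationalizes a
format-independent code.

### Design constants

The generator defaults are the design constants of the emulated study and
are used verbatim by the analysis code:

| constant | value |
|---|---|
| TR | 2 s |
| block duration | 9.6 s |
| blocks per condition per run | 10 |
| voxel size | 2 mm isotropic |
| hemodynamic delay | 6 s |
| volumes averaged per block | 5 |
| SVM | RBF kernel, C = 1, gamma = `scale` |
| voxel-forming threshold | p < 0.005 |
| cluster correction | FDR q < 0.05 |

The spatial sizes used in examples and tests (grids of 11–14 voxels per
axis, spherical gray-matter masks of a few hundred voxels) are package
choices made so that full pipelines run in seconds on one CPU; they are not
constants of the emulated design.

## Synthetic data generation (`mvpa_adapt.simulate`)

One run per participant and format. Block orders are drawn uniformly from
the set of sequences with the exact per-condition block counts and no two
adjacent blocks of the same condition (fixation blocks are interleaved);
feasible orders are counted exactly with a memoized recursion so the draw is
uniform. Each run is `ceil((3·n_blocks·duration + tail)/TR)` volumes with an
8 s tail.

The BOLD signal per voxel is a delayed (6 s) boxcar of the block sequence.
In voxels belonging to a planted effect region, the adaptation /
no-adaptation conditions differ by a multivariate contrast

```
±0.5 · effect_size · noise_sd · (μ + w) / sqrt(1 + μ²),   μ = 0.5
```

where `w = sqrt(c)·shared + sqrt(1−c)·idiosyncratic` mixes a
group/format-shared pattern with a per-participant pattern according to the
`cross_participant_consistency` parameter `c`. With
`shared_across_formats=True`, the same shared pattern is reused for all
formats named by the region, which is what makes between-format transfer
possible; a region listing only `letters` draws an independent pattern, the
specificity control. The normalization keeps the per-voxel contrast variance
independent of `c`.

On top of the signal: white noise (`noise_sd`), a slow polynomial drift, a
constant mean shift, a random-walk motion trace with occasional 3 mm
translation spikes, and intensity spikes of 1.5·SD at the same rate
(`motion_artifact_rate`). A `GroundTruth` object records every planted
region and realized pattern.

## Preprocessing (`mvpa_adapt.preprocess`)

Per run, in order:

1. **Outlier detection.** A volume is flagged if its mean intensity deviates
   more than 3 SD from the run mean, or if any translation parameter moves
   more than 2 mm from the previous volume (rotations are not thresholded;
   the first volume is never motion-flagged).
2. **Repair.** Flagged volumes are replaced by linear interpolation between
   the nearest unflagged neighbours (edge volumes copy the nearest good
   volume). A fully flagged run is an error.
3. **Exclusion.** A participant is excluded if any run has strictly more
   than 20% flagged volumes (exactly 20% is kept). Every exclusion is
   logged with its rule.
4. **Detrending.** A running-median filter with a 61-volume window
   (truncated at the run edges) is subtracted per voxel; runs shorter than
   the window subtract the global median.
5. **Standardization.** Per voxel z-scoring (population SD, `ddof=0`);
   zero-variance voxels are left at zero.
6. **Block averaging.** Each task block contributes one sample: the mean of
   5 volumes starting at `floor((onset + 6 s)/TR)` — volumes {3,…,7} for a
   block at onset 0. Blocks whose window leaves the run are dropped with a
   warning; fixation blocks are skipped.

`build_samples` concatenates all participants into a single `SampleSet` and
returns a participant table (group, IQ, six motion summary covariates) plus
a QC report.

## Searchlight decoding (`mvpa_adapt.searchlight`)

For every gray-matter voxel, the features are the samples of all mask voxels
within the searchlight radius (clipped to the mask). The classifier is a
support-vector machine with RBF kernel, `C = 1` and `gamma = 'scale'`
(`1/(n_features · var)` of the training features), discriminating adaptation
from no-adaptation samples. A fast path calls libsvm directly; setting
`use_fast_svm=False` uses scikit-learn's public `SVC` and produces identical
accuracies.

Decoding schemes (all cross-participant; accuracy is assigned to the sphere
center of the *test* participant's map):

- **within_loocv** — train on all but one participant, test on the held-out
  one, same format. A `("kfold", k)` option groups participants into k folds
  of near-equal size instead.
- **within_crossgroup** — train once on every participant of one group, test
  on each participant of the other group; test maps are independent given
  the training set.
- **between_loocv** — train on all *other* participants' samples in the
  training format, test the held-out participant in the test format; the
  held-out participant's training-format samples are fully excluded.

Map files are named `RawDecAcc_<scheme label>_<participant>.nii` with labels
like `LOOCV_5yo_dots`, `CrossGroup_5yo28yo_dots`, `LOOCV_5yo_dots2digits`,
`10fold_5yo_dots`.

## Group inference (`mvpa_adapt.inference`)

**One-sample sign permutation.** Per voxel, participants' (accuracy − 0.5)
values are sign-flipped; the null is the distribution of flipped means. All
2^P patterns are enumerated when 2^P does not exceed the requested
permutation count, otherwise random patterns are drawn with the identity
pattern always included as the first row (p-values are therefore at least
1/B). `p = #{null ≥ observed}/B`.

**Cluster correction.** Voxels with p below the voxel-forming threshold
(default 0.005) form clusters under 26-connectivity. The cluster null pools
every cluster size from every non-identity permutation; a cluster's p-value
is the fraction of null cluster sizes *strictly larger* than its size, then
Benjamini–Hochberg FDR across the observed clusters (q < 0.05 by default).
`cluster_null="max_stat"` instead compares against the per-permutation
maximum cluster size (with ≥), a familywise-error-controlling alternative.

**Two-sample test.** Group difference of mean maps; the null permutes group
labels.

**Minimum-statistic conjunction.** Two one-sample results (e.g. the two
between-format directions) are combined by the elementwise *maximum* of the
voxel p-values, testing the logical AND; cluster inference then proceeds on
the paired permutation p-matrices.

**Covariate residualization.** Accuracy maps are adjusted by OLS on an
intercept plus six motion summaries and IQ; the *centred* covariate fit is
subtracted so the group mean — and with it the chance-level anchor of the
accuracy scale — is preserved. Collinear columns are dropped with a warning.

**Histogram comparison.** `accuracy_histogram_test` compares two mean-map
accuracy distributions voxelwise with a Wilcoxon signed-rank test.

## Numerical and implementation notes

- Full-pipeline determinism: a single master seed derives all entry seeds
  via `SeedSequence`; repeated runs are byte-identical (provenance JSON
  carries wall-clock runtime and is excluded).
- Monte-Carlo p-values have granularity 1/B, and random sign patterns can
  duplicate the identity pattern by chance, so the smallest achievable
  Monte-Carlo p can exceed 1/B slightly; this is expected binomial behavior,
  not a bug.
- Exhaustive enumeration is refused above 2^22 patterns.
- `benjamini_hochberg` is the classic step-up procedure (monotone cumulative
  minimum of `p·n/rank`).

## Known limitations of the emulated method

Group-level sign-permutation (or t-) tests across **leave-one-participant-out
accuracy maps are anticonservative**: the P fold accuracies share P−2 of
P−1 training participants pairwise, so they are positively correlated
(measured ρ ≈ 0.09 for P = 12 even with independent features), which
inflates the variance of their mean by roughly (1 + (P−1)ρ) ≈ 2 relative to
the independence assumption baked into the sign-flip null. In calibration
runs the per-voxel false-positive rate at nominal 0.05 is ≈ 0.13–0.16, and
the familywise rate of the full null pipeline at the default thresholds is
≈ 0.17 rather than 0.05. This is a property of applying participant-level
exchangeability tests to cross-validated accuracies — the permutation
machinery itself is exactly calibrated on independent maps, and
`within_crossgroup` maps (independent test participants given a fixed
training set) *are* calibrated. The acceptance test
`test_null_pipeline_familywise_error_within_binomial_bound` checks the
nominal bound against the LOOCV pipeline and documents this inflation when
it fails. For calibrated error control, prefer `within_crossgroup` designs
or the `max_stat` cluster null combined with caution about the voxel-level
null.

A second, related mechanism affects **cross-decoding with highly consistent
patterns**: when the training format carries no signal in a voxel but the
test format's pattern there is strongly shared across participants, the
noise-fit classifier is common to all folds, so whenever it happens to align
with the shared test pattern every participant deviates from chance
together. The sign-flip null assumes independent per-participant deviations
and under-covers these heavy tails. In practice this shows up as occasional
tiny (1–3 voxel) significant clusters in otherwise-null between-format
conjunctions (measured in ~3 of 10 simulated datasets at the default
thresholds), even though the conjunction machinery itself is conservative on
independent maps (0/100 familywise errors in calibration runs). The
acceptance test `test_format_independent_code_detected_only_where_planted`
states the strict no-false-positive criterion and fails honestly when this
mechanism fires.
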