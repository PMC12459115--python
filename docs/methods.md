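# Methods

`prososcan` reimplements, as a tested pipeline, an image-classification
analysis of eye-movement scanpaths recorded while subjects with and
without prosopagnosia scan faces in a recognition task.  Because the
original eye-tracking dataset is available only on request, every stage
is driven by a synthetic scanpath generator that plants the group
structure the analysis is designed to detect; the package's claims are
therefore about the *method* (does the pipeline recover structure that
is there, and stay silent when it is not?), not about new clinical data.

## Data model and face template

A fixation is a point (x, y) in image-frame pixel coordinates (origin
top-left, y down), a duration in milliseconds, and a categorical region
of interest (ROI).  Trials are ordered fixation sequences tagged with
subject, group (control / acquired prosopagnosia / developmental
prosopagnosia), task phase and optional response accuracy.  Ten ROIs
cover the face in a fixed canonical order: left eye, right eye, left
eyebrow, right eyebrow, left cheek, right cheek, forehead, nose, mouth,
chin — "left" always meaning the left side of the *image* (the
photographed person's right).

The stimuli behind the original data are nose-centered face photographs
on a 1024×768 screen, but the ROI geometry itself was never published.
The default `FaceTemplate` therefore lays out ten axis-aligned rectangles
on a canonical 300×400 px face box centered on the screen: forehead band
on top, eyebrow and eye bands below it split at the midline, cheeks
flanking a central nose box, then mouth and chin bands.  Points covered
by no region (off-face fixations) are mapped to the nearest region
anchor, ties to the lowest ROI code; whether the original analysis
excluded or remapped off-face fixations is unstated, and remapping keeps
every fixation usable.  Templates serialize to YAML so a
stimulus-specific geometry can be substituted without code changes.

## Synthetic cohorts

Each group is a `GroupProfile`:

* **ROI sequence** — a first-order Markov chain over the 10 ROIs.  The
  first fixation follows an initial distribution peaked on the nose
  (both patients and controls land on the nose first; the stimuli are
  nose-centered).  The three presets use rank-one transition matrices
  (all rows equal to a group "attraction" vector), which is the simplest
  valid chain that plants stationary region preferences and keeps exact
  enumeration oracles tractable.  Per-subject idiosyncrasy adds Gaussian
  noise (sd 0.2) to the transition logits, making each subject's chain
  genuinely first-order and subject-wise cross-validation meaningfully
  harder than trial-wise.
* **Positions** — each fixation lands at its ROI's anchor plus isotropic
  Gaussian jitter (sd 22 px for controls and acquired, 45 px for the
  developmental preset, whose planted signature is spatial dispersion
  rather than a feature-preference shift), then is *re-assigned* an ROI
  from the jittered position, so recorded codes can disagree with the
  latent state near region borders, as in real data.
* **Durations** — i.i.d. log-normal, median ≈ 230 ms, mean ≈ 250 ms
  (fixation durations are right-skewed positive; only the facial
  scanpath encoder consumes them).
* **Trial length** — 1 + NegBinom(r = 10, p = 10/29): mean 20 fixations,
  ~30% of trials shorter than 16, so prefix filtering discards data at
  every m and the m-sweep's information-vs-attrition trade-off is
  exercised.
* **Design** — 45 trials per subject (10 learning + 35 recognition),
  matching the original protocol.

Preset contrast magnitudes are calibrated so the planted effects are of
the order the original analysis reports: the control attraction vector
implies an expected left:right eye index of +0.28 (the reported control
mean), the acquired preset shifts mass to the mouth, nose and right
image eye, and the pipeline's hybrid AUC on a control-vs-acquired preset
cohort comes out near 0.80, the reported headline.  What the generator
does *not* emulate: image-content-driven saliency, saccade dynamics,
drift from the pre-trial fixation cross, phase or accuracy effects, and
any dependence of scanning on the specific face shown.  Passing tests
therefore show that the pipeline recovers planted region-preference and
dispersion structure under subject heterogeneity — not that it would
detect any particular effect in new clinical data.

## Encodings

Both encoders consume only a trial's first m fixations (trials shorter
than m are discarded upstream).

* **Facial scanpath** — each fixation becomes a disc at its scaled
  screen position on a square raster (default 128×128).  Disc radius is
  duration²/constant; the default constant 1500 px·ms² puts a median
  250 ms fixation at ≈ 41 frame px (≈ 4% of frame width) so most discs
  stay within the face box.  Brightness falls linearly with order,
  1 down to 1/m, earliest brightest; overlapping discs combine by
  per-pixel maximum, because additive blending would corrupt the
  brightness-equals-order code.  A zero-duration fixation has zero
  radius and leaves no disc.
* **ROI sequence** — the logical content is an m×10 one-hot matrix (rows
  = temporal order, first at top; columns = ROI), rasterized by
  replicating each cell into a cell_size×cell_size block (default 8).
  Duration is deliberately omitted.  The encoding is exactly invertible;
  `decode_roi_sequence` recovers the codes and is tested to round-trip.

Density overlays sum indicator content (one-hot cells, or binarized disc
masks) across trials, optionally normalized to proportions.

## Classifier

The convolutional network is three blocks of [3×3 convolution, stride 2,
zero-padding 1 → rectifier → 3×3 max-pool, stride 2], with 32, 64 and
128 feature maps, then a flatten and a single sigmoid unit.  Both
spatial operators halve each dimension (ceiling), keeping the three
blocks viable at every raster size the package uses.  The loss is
binary cross-entropy with probabilities clipped at 1e-7; class
imbalance is handled by inverse-frequency sample weights (configurable),
since small synthetic cohorts otherwise admit a constant-majority
solution.  Optimization is Adam; the default schedule (lr 1e-4, up to
100 epochs, batch 32) follows the stated learning rate, with the epoch
chosen by early stopping (patience 10) on the validation subject's loss
— the validation subject exists precisely to select the stopping point.
The implementation is numpy (im2col GEMMs, NHWC, float32) with full
backpropagation, gradient-checked against central finite differences in
float64.

**Cross-validation** rotates the patient subjects: with k patients there
are k folds; fold i tests on patient i, validates on patient i+1
(cyclically), trains on the rest, and controls are dealt round-robin
into k disjoint subsets that rotate alongside.  Every patient is the
test subject exactly once and the validation subject exactly once, and
no subject's trials cross a split boundary.  Each fold is repeated
n_rep times (default 10) with fresh weight initializations and trial
orders; fold performance is the mean test AUC, with the spread across
repetitions reported as reproducibility error bars.

**Hybrid combination**: per fold and repetition, the two encoders'
predictions are averaged with non-negative weights.  Candidates are the
non-negative least-squares solution plus a convex grid (w, 1−w) in steps
of 0.05; the candidate with the highest AUC wins.  AUC depends only on
the weight ratio, so the 1-D grid is exhaustive up to its resolution.
Weights are fit on the fold's *validation* predictions and applied to
its test predictions (fitting them on test predictions would leak).
Ties go to the most balanced weighting, then the lower facial weight; a
component below 0.1% of the total weight is snapped to exactly zero.

**Baseline**: a logistic regression (standardized inputs) on trial
vectors whose first m entries are the ROI codes as plain numeric values
(a one-hot switch exists), followed by engineered features — per-ROI
counts in the first m, mean and total duration, inter-fixation path
length — all toggleable.  The original feature appendix is not available
in the text we work from, so this default set is documented and
replaceable.  The baseline uses the same patient-rotation subject-wise
folds as the network (validation subjects joining the training side).
Sweeping m over 2..20 yields the AUC-vs-m curve; the optimal m is its
argmax, ties to the smallest m.  With the presets' stationary planted
biases the synthetic curve rises with m rather than forming the
inverted U expected when group differences concentrate in early
fixations and attrition bites harder.

## Statistics

* **Permutation test** — group labels are permuted across *subjects*
  (never trials), preserving group sizes and the subject-wise CV
  structure; the pipeline is retrained per permutation and
  p = (1 + #{null AUC ≥ true AUC})/(1 + n_perm).  The add-one convention
  avoids p = 0 and matches reporting "p < 0.01" when 0 of 100
  permutations exceed truth.  With 16 subjects the null is right-shifted
  above 0.5 (a permuted labeling can overlap the true one in up to 7 of
  8 patients), which is why a wide truth-null margin matters.
* **Scan indices** — left:right = (L−R)/(L+R) over eye fixations,
  eye:mouth = (E−M)/(E+M), both over the first m fixations of trials
  with ≥ m; dispersion = per-subject mean of the per-trial sample SD of
  fixation distances from the face center (default m = 16).  Subjects
  with empty denominators are excluded and flagged, not errored.
* **ROI contrast** — per fixation row of an m×10 count matrix, contrast
  is the coefficient of variation (population SD / mean) of the ten
  counts: scale-free (overlays with different trial counts are
  comparable), 0 for a uniform row, 3.0 for a one-hot row.  Michelson or
  plain SD were alternatives; CV was chosen for the scale-freeness.
  Group × fixation-number effects are assessed with a two-way
  repeated-measures (mixed) ANOVA over train-test repetitions.
* **Signal detection** — d′ = z(H) − z(F), c = −(z(H)+z(F))/2, with
  extreme rates corrected by 1/(2N) before the probit transform.
* **Group tests** — one-way ANOVA, one-tailed two-sample t-tests with
  pooled variance (Welch selectable), Pearson correlations.  Degrees of
  freedom are reported from the data actually supplied.

## Desk-scale configuration and problem sizes

The full-size configuration (128 px rasters, 10 repetitions, 100
epochs) is the package default.  Tests and the acceptance script use
`PipelineConfig.reduced()` — 16 px facial rasters, 2 px ROI cells, 12
epochs at lr 1e-3, 1 repetition — which preserves every structural
element (both encoders, k-fold subject rotation, validation-fit hybrid
weights) at sizes where hundreds of retrainings are feasible: the
planted-signal study uses 8+8 subjects × 45 trials, its 100-permutation
null uses the same design subsampled to 16 trials per subject, and the
null-calibration study uses 20 seeds × 19 permutations on 4+4 subjects
× 8 trials.  Null cohorts are generated without subject heterogeneity:
with idiosyncratic per-subject chains the subject-wise fold AUC
fluctuates far beyond the trial-count chance band even when no group
difference exists, so the exchangeable null is the right calibration
target.

## Known limitations

* The numpy network is CPU-bound and meant for rasters up to ~128 px;
  it is not a general-purpose deep-learning stack.
* Rank-one preset chains make ROI draws i.i.d. after the first
  fixation; sequential effects beyond "nose first" are only introduced
  indirectly by subject heterogeneity.
* The published recognition-score table is reproduced at its printed
  2-decimal precision; statistics recomputed from it inherit that
  rounding.
* Real hit/false-alarm counts behind the published d′ values are not
  printed, so d′ recomputation from raw counts cannot be checked against
  them — only against closed-form oracles.
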