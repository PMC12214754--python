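# Methods

This note documents the models implemented in `posexis`, the assumptions of
the synthetic data generator, and the numerical choices made where the
design was genuinely open. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Keypoint data matrices

Each stimulus is a configuration of 22 labeled skeletal keypoints seen from
one camera. The data matrix `X` has one stimulus per row and one scaled
coordinate per column, interleaved per keypoint (`x1, y1[, z1], x2, ...`).
All coordinates — including the inferred depth z — are divided by the image
size (350 px), so values lie in [0, 1]; z is the signed distance from the
frontal plane through the pelvis and can be negative.

The five variants express viewpoint hypotheses by row operations, never by
mirroring coordinates:

* **2D / 3D_VD** — the rendered coordinates as-is (view-dependent).
* **2D_VF / 3D_VF** — rows at azimuths 315/270/225 deg are replaced by the
  rows of the same pose and elevation at 45/90/135 deg, so mirror-symmetric
  views share a representation. The reverse replacement direction is
  available (`reverse=True`) as a control. The operation is idempotent.
* **3D_VI** — every azimuth's row is replaced by the 0-deg row of its
  (pose, elevation) group; only fully rotation-tolerant responses can be
  fitted well by this variant.

### The two view-flipped constructions

The view-flipped model can also be built without refitting PCA: keep the
view-dependent basis and equate the PC *scores* of mirrored views
(`flip_scores`). Row replacement leaves the score columns with non-zero
means, which would bias the no-intercept regression, so the equated scores
are recentred by default — PC-score predictors are zero-mean by
construction, and the regression relies on that. With recentring, the two
constructions produce unit-level predictive performances that correlate
near-perfectly across synthetic populations (recomputed by
`scripts/acceptance.py`).

## PCA

PCA is fitted on the full data matrix of all stimuli (columns demeaned),
not per cross-validation fold: the stimulus set is a fixed, noise-free
design, so its principal directions are a property of the stimuli rather
than of any unit's responses, and sharing them across folds is deliberate.
The response-side standardization does have a per-fold mode (below). Defaults: 10 components for keypoint matrices,
50 for pixel/feature-bank matrices (both configurable).

Component signs are fixed by making each component's largest-magnitude
loading positive, so bases, scores, and everything derived from them are
reproducible bit-for-bit. `sds` stores the score standard deviations
(square roots of the eigenvalues, ddof = 1). If the matrix rank falls below
the requested component count, the available components are returned with a
warning.

## Encoding model

Per unit, the across-trial mean response-window rate per stimulus is
z-scored **once across all stimuli** (the "global" mode, default) and
regressed on the PC scores with 10-fold cross-validation, ordinary least
squares, and no intercept. The z-scoring scope was an open choice; global
scoring keeps the held-out fold's statistic well defined under a single
fixed transformation and matches the use of one preferred axis per unit
downstream. A `per_fold` mode (training-fold mean/sd applied to train and
test) is available; it also makes the fold betas exactly independent of
held-out responses, which the test suite exploits.

Numerical choices:

* Fold assignment is a seeded, unstratified random partition into 10 equal
  blocks; one seed per unit by default (callers can share seeds across fits
  when coherence is required, e.g. variance partitioning).
* The solve uses `lstsq` (SVD), so a rank-deficient design falls back to
  the minimum-norm pseudoinverse solution instead of failing — this also
  makes redundant predictors in combined models harmless.
* A held-out fold with zero response variance yields R² = −inf (the honest
  limit of the formula); this is only reachable at toy problem sizes.
* Negative cross-validated R² is propagated as-is everywhere.

Scores: adjusted R² uses `1 − (1 − R²)(N − 1)/(N − M − 1)` with N the
stimulus count and M the predictor count. Both R² and adjusted R² are
divided by the unit's split-half reliability (the noise ceiling); the
normalization requires r > 0 and is left undefined otherwise.

### Permutation nulls

Three schemes, all seeded: full-refit label shuffling (primary), test-only
label shuffling (labels permuted within each held-out fold after fitting
with true labels), and beta permutation (fitted coefficients permuted
across the K components before prediction). Explicit permutation lists can
be supplied for audits; an identity permutation reproduces the observed
statistic exactly.

## Unit screening

Five criteria combined with AND, thresholds configurable with these
defaults: split-plot ANOVA of window (baseline vs response, repeated) by
stimulus (between-presentation), pass if either the window main effect or
the interaction has p < 0.05; Fano slope (OLS of per-stimulus spike-count
variance on mean count) < 4; maximum over stimuli of the mean net rate
> 5 spikes/s; Kruskal–Wallis stimulus effect p < 0.05; Spearman–Brown
corrected split-half reliability > 0.5. Units with a category test are
additionally screened for a Body Selectivity Index >= 0.33 (net body rates
vs net face+object rates) with a significant category response.

The split-plot ANOVA is computed from closed-form balanced sums of squares
(window and interaction both tested against the window-by-presentation
error term), vectorized across units; it is verified against
`pingouin.mixed_anova` in the test suite. Split-half reliability averages
100 seeded random splits; a single split is an unbiased but noisy estimate,
and averaging stabilizes it (the single-split mode is the `n_splits=1`
case). With odd trial counts the extra trial goes to the first half of
that split.

## Axis inversion

Eigenposes `e_iκ = X̄ + κσᵢpᵢ`; axis image `t̂ = Pβ̂` reshaped to 22 rows;
weights are row magnitudes; poses along the axis use `b̂ᵢ = σᵢβ̂ᵢ`, i.e.
`a_κ = X̄ + κ Σ σᵢ²β̂ᵢpᵢ`. Weight significance: stimulus labels shuffled,
model refitted (full cross-validation by default; a cheaper single
full-data fit behind `refit="full"`), weights recomputed; one-sided p =
fraction of null weights >= observed; Benjamini–Hochberg across the 22
keypoints at alpha = 0.05. For display, non-significant weights are zeroed
**before** max-normalization (the order was unspecified; zeroing first
keeps the strongest significant keypoint at 1).

## View Invariance Index

Model responses `ŷ = (X − X̄)Pβ̂` are the stimulus distances along the
preferred axis. The (pose, elevation) combination containing the global
maximum (ties broken by lowest stimulus index) defines the observed range
r_o over its 8 azimuths. The null draws 7 responses from the 712 stimuli
outside the best combination (the "remaining" pool excludes all 8 of its
views — the arithmetic 720 − 8 = 712 fixes this reading), adds the maximum,
and takes the range; 1000 seeded draws without replacement within a draw.
`VII = −(r_o − μ_null)/σ_null`. The index is invariant to positive affine
transforms of `ŷ` and errors out when the null is degenerate (constant
responses). Population summaries gate VII on unnormalized R² > 0.25.

## Population analyses

**Variance partitioning.** `unique_A = R²_comb − R²_B`, `unique_B = R²_comb
− R²_A`, `shared = R²_A + R²_B − R²_comb`, requiring identical fold
assignments across the three fits; components may be negative and are
reported as-is.

**Clustering.** `sklearn.cluster.HDBSCAN` with `min_cluster_size = 2`,
`min_samples = 2` on the units' preferred axes (callers gate on
R² > 0.25); label −1 marks unclustered units. Each cluster is summarized
by its medoid (minimum summed within-cluster Euclidean distance) and the
median/quartiles of supplied metrics. A zero-spread population (all axes
identical) is defined as a single cluster, since a density-based method
sees no gradient there.

**Decoding.** All views of a pose share its label. Per resample, each
unit's presentations within a pose are independently shuffled and
concatenated position-wise into pseudo-population trials (16 views x
n_trials per pose, optionally capped for desk-scale runs);
leave-one-pseudo-trial-out cross-validation; the max-correlation classifier
assigns the class whose training-mean template has the highest Pearson
correlation with the test vector (ties: lowest class index). Accuracy and
the column-normalized confusion matrix (columns = true class, sum to 100%)
are averaged over 50 resamples. An optional label-permutation null reruns
the procedure on permuted pose labels and reports the maximum mean
accuracy. A linear SVM variant (one-vs-rest, C = 1) is provided; it is
much slower under leave-one-out and intended for small problems.

## Synthetic data generator

The generator defines the study conditions for all tests.

**Stimuli.** A 22-keypoint kinematic tree (head/neck/arms/spine/pelvis/
legs/tail; labels are placeholders — only the count and tree structure
matter downstream) is posed by named joint angles. Nine behavioural classes
(sitting, eating, hanging, laying, standing, walking, reaching, crouching,
climbing) define class-mean angles; the 45 poses are 5 exemplars per class,
drawn with a 7-degree within-class spread, left and right limbs drawn
independently. Each pose is rendered at 8 azimuths (45-degree steps) for
camera elevations 0 and 45 degrees by orthographic projection aimed at the
pelvis; for the hanging class the elevated cameras sit below the horizontal
plane looking up 45 degrees. One global scale maps twice the maximum
pelvis-relative half-extent across all stimuli onto the image size — with
the pelvis as the projection center this guarantees every x, y lies on the
canvas while the widest stimulus spans (up to symmetry) the full image.
Silhouettes rasterize the bones as thick segments (half-width ~1.5% of the
image) and block-max downsample to 25 x 25.

**Units.** Each unit's ground-truth axis is uniform on the unit sphere of
the PC space of its generative variant; the mean rate is
`rectify(baseline + gain * Z β_true)` with baseline 10 spikes/s, and trials
are Poisson counts over the 200 ms response window converted to rates
(Gaussian and noise-free options exist). Rectification keeps Poisson means
valid; it is a documented deviation from pure linearity, negligible while
the baseline dominates the modulation. The gain is calibrated by bisection
on its logarithm so the population's median split-half reliability hits the
target (default 0.7, internal tolerance 0.02, 20 splits per evaluation,
common random numbers across evaluations for monotonicity). Baseline-window
rates are Poisson over 100 ms. The category test emits 20/20/20
body/face/object movies with configurable net gains over a 5-spikes/s
baseline (1 s response window, 200 ms baseline window).

**Feature bank.** A surrogate image-computable bank: seeded Gaussian random
projections of silhouette pixels (or of a keypoint matrix) through a
pointwise nonlinearity (default rectification), exposing the same matrix
interface as any other data matrix.

**What the generator does not emulate.** No texture, shading, occlusion or
local body-part form — the silhouettes are stick figures, and the feature
bank is a random projection, not a trained network. Pose classes are
synthetic and only need to be mutually distinguishable; they do not match
any particular behavioural repertoire. Trial noise is exactly Poisson
(Fano = 1), cleaner than real recordings. Consequently, passing tests show
that the *analysis chain* is correct and well calibrated under its own
assumptions — recovery of planted axes, correct null behavior, correct
dissociation of viewpoint hypotheses — not that real neurons obey the
model. One concrete ceiling: view-invariant 45-way pose decoding from
these 25 x 25 stick silhouettes (or raw keypoints) by any linear readout
plateaus near 25–30%, roughly 10x chance but far below what richer images
could support; the corresponding test asserts the computed property
(accuracy well above chance), not an absolute level.

## Problem sizes

The default test and acceptance runs use 50-unit populations per generative
variant at target reliability 0.7 with 6 trials per stimulus, 100–300
permutations/resamples for null distributions, and reduced pseudo-trial
counts for decoding; these sizes give stable medians and tight nulls while
keeping the full suite in the minutes range on one CPU. The pipeline's
`test_mode` lowers permutation and resample counts only — formulas never
change.

## Known limitations

* The regression has no intercept (by construction of the model); with
  globally centered scores and z-scored responses the omitted-intercept
  bias is second order, but per-fold training subsets are not exactly
  centered.
* Weight-significance nulls refit the cross-validated model; with very low
  permutation counts the p-value resolution is coarse (a warning fires
  below 20).
* The SVM decoding variant is O(n_trials) full refits under leave-one-out.
* `fit_pca` is dense SVD; it is sized for hundreds-to-thousands of rows
  and columns, not for very wide CNN-activation matrices.
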