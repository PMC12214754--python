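# posexis

Keypoint-based encoding models of body **pose** and **viewpoint** tuning in
visual neurons.

Neurons in the primate superior temporal sulcus respond selectively to body
images, but with hundreds of poses seen from many vantage points it is hard
to say *which* visual features drive a given cell. This package implements a
model-based answer: parameterize each stimulus by the image coordinates of
22 skeletal keypoints, reduce them with PCA, and fit each unit's response
with a cross-validated linear regression on the principal-component scores.
Because every step is linear, the fitted model can be *inverted* — the
regression coefficients define a "preferred axis" whose keypoint-space image
shows which body parts drive the selectivity, and walking along the axis
renders the poses the unit prefers.

It is aimed at systems neuroscientists who want to fit, test, and dissect
such models on their own recordings, and it ships a complete synthetic
stimulus/response generator so that every stage of the analysis is testable
without any recorded data.

## The model

For the 720-stimulus grid (45 poses x 16 views), a data matrix
`X ∈ R^(720×d)` stacks the scaled keypoint coordinates of each stimulus
(d = 44 for 2D, 66 for 3D). Five variants encode viewpoint hypotheses:

| variant | content |
|---|---|
| `2D` | image-plane (x, y) keypoints, view-dependent |
| `3D_VD` | camera-aligned (x, y, z) keypoints, view-dependent |
| `2D_VF` / `3D_VF` | "view-flipped": mirror-symmetric azimuths (45/315, 90/270, 135/225 deg) share one representation |
| `3D_VI` | "view-invariant": all azimuths of a pose share the 0 deg representation |

With `P` the first K = 10 principal components of `X` and `Z = (X − X̄)P`
the scores, each unit's z-scored stimulus-mean response `y` is fitted with
10-fold cross-validation and no intercept:

```
β̂_k = (Z_kᵀ Z_k)⁻¹ Z_kᵀ y_k          R²_k = 1 − Σ(y − ŷ)² / Σ(y − ȳ)²   (held-out fold)
```

The unit's preferred axis `β̂` and `R²` are fold averages; `R²` is corrected
for predictor count (`R²_adj`) and divided by the unit's Spearman–Brown
split-half reliability `r` (the noise ceiling) to give `R̃² = R²/r`.
Inversion products: eigenposes `e_iκ = X̄ + κσᵢpᵢ`, the keypoint image of
the axis `t̂ = Pβ̂` with per-keypoint weights `wᵢ = ‖Tᵢ‖` (permutation-FDR
screened), poses along the axis `a_κ = X̄ + κ Σ σᵢ²β̂ᵢpᵢ`, and a View
Invariance Index `VII = −(r_o − μ_null)/σ_null` comparing the response range
over the best pose's 8 views with ranges of random response draws.
Population tools: variance partitioning against an alternative feature bank,
HDBSCAN clustering of preferred axes with medoid summaries, and
pseudo-population decoding of pose (irrespective of viewpoint) with a
leave-one-out max-correlation classifier.

## Worked example

```python
import numpy as np
import posexis as px

# 1. stimuli: 45 poses x 16 views of a 22-keypoint skeleton
pose_set = px.generate_pose_set(n_poses=45, n_views=16, seed=1)
matrix = px.build_data_matrix(pose_set, "2D")
basis = px.fit_pca(matrix, n_components=10)
scores = basis.project(matrix.X)
print(f"stimuli: {pose_set.n_stimuli}, data matrix: {matrix.X.shape}, "
      f"PC variance: {basis.explained_variance_ratio.sum():.2f}")

# 2. simulate a unit tuned along a hidden axis, reliability ~0.7
unit = px.simulate_encoding_units(scores, n_units=1, target_reliability=0.7,
                                  n_trials=6, seed=3, variant="2D")[0]
reliability = px.split_half_reliability(unit.response_rates, seed=0)

# 3. fit the cross-validated PC regression and invert it
fit = px.fit_pcr_cv(scores, unit.mean_response, seed=5,
                    reliability=reliability)
beta_true = np.array(unit.ground_truth["beta_true"])
cosine = abs(fit.beta @ beta_true) / (
    np.linalg.norm(fit.beta) * np.linalg.norm(beta_true))
weights = px.keypoint_weights(px.axis_to_keypoints(basis, fit.beta))
top = pose_set.keypoint_labels[int(np.argmax(weights))]
print(f"reliability r = {reliability:.2f}, R2 = {fit.r2:.2f}, "
      f"R2/r = {fit.r2_norm:.2f}")
print(f"axis recovery cos = {cosine:.3f}, strongest keypoint: {top}")

# 4. viewpoint tolerance of the fitted axis
y_hat = px.predict_model_responses(matrix, basis, fit.beta)
vii = px.compute_vii(y_hat, matrix.index, seed=7)
print(f"VII = {vii.vii:.2f} (range {vii.observed_range:.3f} over the best "
      f"pose's 8 views)")
```

prints

```
stimuli: 720, data matrix: (720, 44), PC variance: 0.99
reliability r = 0.69, R2 = 0.66, R2/r = 0.96
axis recovery cos = 0.929, strongest keypoint: l_foot
VII = -0.06 (range 3.034 over the best pose's 8 views)
```

The simulated unit's split-half reliability lands at the 0.7 target; the
cross-validated model explains 66% of its response variance — 96% of what
its noise ceiling allows — and recovers the hidden tuning axis (cosine
0.93). The inversion says the left foot's position contributes most, and the
VII near zero says the fitted axis is about as view-tolerant as chance: its
preferred pose still depends on vantage point.

The same chain runs end to end from a config file:

```sh
posexis all --config run.yaml --seed 7     # or: posexis simulate|select|fit|... 
```

which simulates stimuli and units, screens units (responsivity, Fano
factor, net rate, selectivity, reliability, body-selectivity index), fits
all five variants per unit, inverts the axes, computes VII, partitions
variance against a surrogate feature bank, clusters the axes, decodes pose,
and writes a manifest with checksummed artifacts.

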