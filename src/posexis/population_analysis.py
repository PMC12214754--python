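"""Population-level analyses: variance partitioning, axis clustering, and
view-invariant pose decoding.

Variance partitioning splits a unit's cross-validated explained variance
between two feature banks (e.g. keypoints vs an image-computable bank):

    unique_A = R2_combined - R2_B
    unique_B = R2_combined - R2_A
    shared   = R2_A + R2_B - R2_combined

Preferred axes are clustered with HDBSCAN (min_cluster_size = 2,
min_samples = 2) and summarized by their medoids.  Decoding assembles
pseudo-population responses per pose (all viewpoints share the pose label)
and classifies them with a leave-one-out max-correlation classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist
from sklearn.cluster import HDBSCAN


@dataclass
class VariancePartition:
    """Unique and shared explained variance of two predictor banks."""

    unit_id: str | None
    r2_a: float
    r2_b: float
    r2_combined: float
    unique_a: float
    unique_b: float
    shared: float


def variance_partition(fit_a, fit_b, fit_combined) -> VariancePartition:
    """Partition cross-validated R2 between two banks (identical CV folds).

    Components can be negative (cross-validated R2 is not bounded below)
    and are reported as-is.
    """
    if not np.array_equal(fit_a.fold_assignment, fit_b.fold_assignment) or not (
        np.array_equal(fit_a.fold_assignment, fit_combined.fold_assignment)
    ):
        raise ValueError("all three fits must use identical fold assignments")
    ra, rb, rc = fit_a.r2, fit_b.r2, fit_combined.r2
    return VariancePartition(
        unit_id=fit_a.unit_id, r2_a=ra, r2_b=rb, r2_combined=rc,
        unique_a=rc - rb, unique_b=rc - ra, shared=ra + rb - rc,
    )


@dataclass
class ClusterResult:
    """HDBSCAN labels of the units' preferred axes plus cluster summaries.

    ``labels`` uses -1 for unclustered ("None") units.  ``summaries`` maps
    each cluster label to a dict with the medoid unit position, member
    count, and median [25th, 75th percentile] of any metrics supplied.
    """

    labels: np.ndarray
    medoids: dict[int, int]
    summaries: dict[int, dict]
    min_cluster_size: int
    min_samples: int

    @property
    def n_clusters(self) -> int:
        return len(self.medoids)


def cluster_axes(
    betas: np.ndarray,
    min_cluster_size: int = 2,
    min_samples: int = 2,
    metrics: dict[str, np.ndarray] | None = None,
) -> ClusterResult:
    """Density-cluster preferred axes and summarize each cluster.

    ``betas`` is units x K (callers should gate units on model validity,
    e.g. R2 > 0.25, before clustering).  The medoid of a cluster minimizes
    the summed within-cluster Euclidean distance.  ``metrics`` (e.g.
    ``{"r2": ..., "vii": ...}``) are summarized per cluster by median and
    quartiles.
    """
    B = np.asarray(betas, dtype=float)
    if B.ndim != 2 or B.shape[0] < 2:
        raise ValueError("need >= 2 units to cluster")
    if np.all(B == B[0]):
        # degenerate zero-spread input: HDBSCAN sees no density gradient and
        # marks everything noise; identical axes are by definition one cluster
        info: dict = {"n": int(B.shape[0]), "medoid": 0}
        for name, vals in (metrics or {}).items():
            v = np.asarray(vals, dtype=float)
            info[name] = {
                "median": float(np.median(v)),
                "q25": float(np.percentile(v, 25)),
                "q75": float(np.percentile(v, 75)),
            }
        return ClusterResult(
            labels=np.zeros(B.shape[0], dtype=int), medoids={0: 0},
            summaries={0: info},
            min_cluster_size=min_cluster_size, min_samples=min_samples,
        )
    labels = HDBSCAN(
        min_cluster_size=min_cluster_size, min_samples=min_samples, copy=True
    ).fit_predict(B)

    dist = squareform(pdist(B))
    medoids: dict[int, int] = {}
    summaries: dict[int, dict] = {}
    for lab in sorted(set(labels) - {-1}):
        members = np.flatnonzero(labels == lab)
        sub = dist[np.ix_(members, members)]
        medoids[lab] = int(members[np.argmin(sub.sum(axis=1))])
        info: dict = {"n": int(members.size), "medoid": medoids[lab]}
        for name, vals in (metrics or {}).items():
            v = np.asarray(vals, dtype=float)[members]
            info[name] = {
                "median": float(np.median(v)),
                "q25": float(np.percentile(v, 25)),
                "q75": float(np.percentile(v, 75)),
            }
        summaries[lab] = info
    return ClusterResult(
        labels=labels, medoids=medoids, summaries=summaries,
        min_cluster_size=min_cluster_size, min_samples=min_samples,
    )


@dataclass
class DecodingResult:
    """Pose-decoding accuracy, its spread, and the confusion matrix.

    ``confusion`` is predicted x true in percent; each column sums to 100.
    ``perm_max`` is the maximum mean accuracy over label permutations
    (populated when a permutation null was requested).
    """

    accuracy: float
    accuracy_sd: float
    confusion: np.ndarray
    classes: np.ndarray
    n_resamples: int
    classifier: str
    chance_level: float
    perm_max: float | None
    seed: int


def _pseudo_trials(
    rates: np.ndarray, class_of: np.ndarray, classes: np.ndarray,
    rng: np.random.Generator, cap: int | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble pseudo-trials: (n_samples, n_units) plus class labels.

    ``rates`` is (n_units, n_trials, n_stimuli).  For each class, every
    unit's presentations (all trials of all stimuli in the class) are
    independently shuffled, then concatenated position-wise across units.
    """
    n_units = rates.shape[0]
    xs, ys = [], []
    for ci, cl in enumerate(classes):
        cols = np.flatnonzero(class_of == cl)
        block = rates[:, :, cols].reshape(n_units, -1)  # (units, presentations)
        n_pres = block.shape[1]
        take = n_pres if cap is None else min(cap, n_pres)
        idx = np.stack([rng.permutation(n_pres)[:take] for _ in range(n_units)])
        xs.append(np.take_along_axis(block, idx, axis=1).T)
        ys.append(np.full(take, ci))
    return np.vstack(xs), np.concatenate(ys)


def _loo_max_correlation(X: np.ndarray, y: np.ndarray, n_classes: int) -> np.ndarray:
    """Leave-one-out max-correlation classification; returns predictions.

    The left-out sample is assigned the class whose training-mean template
    has the highest Pearson correlation with it (ties: lowest class index).
    """
    sums = np.zeros((n_classes, X.shape[1]))
    counts = np.zeros(n_classes)
    for ci in range(n_classes):
        sums[ci] = X[y == ci].sum(axis=0)
        counts[ci] = np.sum(y == ci)
    if np.any(counts < 2):
        raise ValueError("each class needs >= 2 pseudo-trials for leave-one-out")
    preds = np.empty(X.shape[0], dtype=int)
    for i in range(X.shape[0]):
        templates = sums / counts[:, None]
        templates[y[i]] = (sums[y[i]] - X[i]) / (counts[y[i]] - 1)
        t = templates - templates.mean(axis=1, keepdims=True)
        x = X[i] - X[i].mean()
        denom = np.sqrt((t**2).sum(axis=1) * (x**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(denom > 0, t @ x / denom, -np.inf)
        preds[i] = int(np.argmax(corr))
    return preds


def _loo_linear_svm(X: np.ndarray, y: np.ndarray, n_classes: int) -> np.ndarray:
    from sklearn.svm import LinearSVC

    preds = np.empty(X.shape[0], dtype=int)
    for i in range(X.shape[0]):
        mask = np.ones(X.shape[0], dtype=bool)
        mask[i] = False
        clf = LinearSVC(C=1.0, multi_class="ovr", dual="auto")
        clf.fit(X[mask], y[mask])
        preds[i] = int(clf.predict(X[i : i + 1])[0])
    return preds


def decode_poses(
    rates: np.ndarray,
    pose_labels: np.ndarray,
    classifier: str = "max_correlation",
    n_resamples: int = 50,
    n_label_perms: int = 0,
    max_pseudotrials: int | None = None,
    seed: int = 0,
) -> DecodingResult:
    """Decode pose identity, irrespective of viewpoint, from a population.

    ``rates`` is (n_units, n_trials, n_stimuli); ``pose_labels`` assigns
    every stimulus its pose id (all views of a pose share the label).  Per
    resample, pseudo-population trials are built by independently shuffling
    each unit's presentations within a pose, then classified with
    leave-one-out cross-validation.  ``max_pseudotrials`` caps the
    pseudo-trials per pose (desk-scale runs).  With ``n_label_perms > 0``
    the whole procedure is rerun on permuted pose labels (one resample
    each) and the maximum mean accuracy is reported as the null.
    """
    if classifier == "max_correlation":
        loo = _loo_max_correlation
    elif classifier == "linear_svm":
        loo = _loo_linear_svm
    else:
        raise ValueError(f"unknown classifier: {classifier!r}")
    rates = np.asarray(rates, dtype=float)
    if rates.ndim != 3:
        raise ValueError("rates must be (n_units, n_trials, n_stimuli)")
    if rates.shape[1] < 2:
        raise ValueError("need >= 2 trials per stimulus")
    pose_labels = np.asarray(pose_labels)
    classes = np.unique(pose_labels)
    n_classes = classes.size
    rng = np.random.default_rng(seed)

    def run(labels: np.ndarray, resamples: int) -> tuple[float, float, np.ndarray]:
        accs = np.empty(resamples)
        conf = np.zeros((n_classes, n_classes))  # predicted x true
        for r in range(resamples):
            X, y = _pseudo_trials(rates, labels, classes, rng, max_pseudotrials)
            preds = loo(X, y, n_classes)
            accs[r] = np.mean(preds == y)
            np.add.at(conf, (preds, y), 1.0)
        conf = 100.0 * conf / conf.sum(axis=0, keepdims=True)
        return float(accs.mean() * 100), float(accs.std() * 100), conf

    acc, sd, confusion = run(pose_labels, n_resamples)

    perm_max = None
    if n_label_perms > 0:
        best = -np.inf
        for _ in range(n_label_perms):
            perm_labels = pose_labels[rng.permutation(pose_labels.size)]
            a, _, _ = run(perm_labels, 1)
            best = max(best, a)
        perm_max = float(best)

    return DecodingResult(
        accuracy=acc, accuracy_sd=sd, confusion=confusion, classes=classes,
        n_resamples=n_resamples, classifier=classifier,
        chance_level=100.0 / n_classes, perm_max=perm_max, seed=seed,
    )
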