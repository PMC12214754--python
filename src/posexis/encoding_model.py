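"""Cross-validated principal-component regression of unit responses.

Each unit's stimulus-mean response (z-scored once, across all stimuli) is
regressed on the PC scores of a data-matrix variant with 10-fold
cross-validation and no intercept:

    beta_k = (Z_k' Z_k)^{-1} Z_k' y_k          (training folds, 648 of 720)
    yhat_k' = Z_k' beta_k                      (held-out fold)
    R2_k = 1 - sum (y - yhat)^2 / sum (y - ybar)^2   (held-out stimuli)

The unit's preferred axis beta and its R2 are the averages over folds.
Scores are corrected for the number of predictors (adjusted R2) and for the
unit's split-half reliability r, the noise ceiling: Rt2 = R2 / r.  Null
distributions of the reliability-normalized score come from three
permutation schemes (full-refit label shuffling, test-only label shuffling,
and beta permutation across PCs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class EncodingFit:
    """Per-unit fit: fold-wise and averaged axes and performance scores."""

    unit_id: str | None
    variant: str | None
    K: int
    n_folds: int
    fold_assignment: np.ndarray   # (n_stimuli,) fold label of each stimulus
    betas: np.ndarray             # (n_folds, K)
    r2_folds: np.ndarray          # (n_folds,)
    beta: np.ndarray              # (K,) mean over folds: the preferred axis
    r2: float
    r2_adj: float
    reliability: float | None = None
    r2_norm: float | None = None       # R2 / reliability
    r2_adj_norm: float | None = None   # adjusted R2 / reliability
    seed: int | None = None


@dataclass
class NullDistribution:
    """Permutation null of the reliability-normalized R2."""

    method: str
    values: np.ndarray
    seed: int | None

    @property
    def n_perm(self) -> int:
        return self.values.size

    @property
    def percentiles(self) -> tuple[float, float]:
        return (
            float(np.percentile(self.values, 2.5)),
            float(np.percentile(self.values, 97.5)),
        )


def fold_split(n: int, n_folds: int, seed: int) -> np.ndarray:
    """Seeded unstratified random partition into ``n_folds`` equal blocks."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    for k, block in enumerate(np.array_split(perm, n_folds)):
        assignment[block] = k
    return assignment


def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Adjusted coefficient of determination, 1 - (1-R2)(N-1)/(N-M-1)."""
    if n <= m + 1:
        raise ValueError("adjusted R2 requires N > M + 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def performance_metrics(
    r2: float, n: int, m: int, reliability: float
) -> tuple[float, float, float, float]:
    """(R2, adjusted R2, both divided by the reliability noise ceiling).

    Negative R2 (model worse than the held-out mean) propagates as-is.
    """
    if reliability <= 0:
        raise ValueError("reliability must be > 0 for noise-ceiling normalization")
    r2a = adjusted_r2(r2, n, m)
    return r2, r2a, r2 / reliability, r2a / reliability


def _zscore(y: np.ndarray) -> np.ndarray:
    sd = y.std()
    if sd == 0:
        raise ValueError("constant response: z-score undefined")
    return (y - y.mean()) / sd


def _cv_fit(
    Z: np.ndarray, y: np.ndarray, assignment: np.ndarray, n_folds: int
) -> tuple[np.ndarray, np.ndarray]:
    """Fold-wise no-intercept OLS (pseudoinverse via lstsq) and held-out R2."""
    betas = np.empty((n_folds, Z.shape[1]))
    r2s = np.empty(n_folds)
    for k in range(n_folds):
        test = assignment == k
        train = ~test
        beta, *_ = np.linalg.lstsq(Z[train], y[train], rcond=None)
        betas[k] = beta
        yhat = Z[test] @ beta
        resid = np.sum((y[test] - yhat) ** 2)
        total = np.sum((y[test] - y[test].mean()) ** 2)
        # a zero-variance held-out fold gives R2 = -inf (model cannot beat a
        # constant it already equals); only reachable at toy problem sizes
        with np.errstate(divide="ignore"):
            r2s[k] = 1.0 - resid / total
    return betas, r2s


def fit_pcr_cv(
    scores: np.ndarray,
    y: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
    zscore: str = "global",
    reliability: float | None = None,
    unit_id: str | None = None,
    variant: str | None = None,
) -> EncodingFit:
    """Fit the cross-validated PCR encoding model of one unit.

    ``scores`` are the PC scores Z (stimuli x K) of a data-matrix variant;
    ``y`` is the across-trial mean response per stimulus.  ``zscore``
    selects the response standardization: ``"global"`` (one fixed transform
    over all stimuli; default) or ``"per_fold"`` (training-fold mean/sd
    applied to train and test).  Supplying ``reliability`` also populates
    the noise-ceiling-normalized scores.
    """
    Z = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, K = Z.shape
    if y.size != n:
        raise ValueError("y must have one value per stimulus")
    if K >= n - n // n_folds:
        raise ValueError("more predictors than training stimuli")
    assignment = fold_split(n, n_folds, seed)

    if zscore == "global":
        yz = _zscore(y)
        betas, r2s = _cv_fit(Z, yz, assignment, n_folds)
    elif zscore == "per_fold":
        betas = np.empty((n_folds, K))
        r2s = np.empty(n_folds)
        for k in range(n_folds):
            test = assignment == k
            train = ~test
            mu, sd = y[train].mean(), y[train].std()
            if sd == 0:
                raise ValueError("constant training response: z-score undefined")
            beta, *_ = np.linalg.lstsq(Z[train], (y[train] - mu) / sd, rcond=None)
            betas[k] = beta
            yt = (y[test] - mu) / sd
            yhat = Z[test] @ beta
            r2s[k] = 1.0 - np.sum((yt - yhat) ** 2) / np.sum((yt - yt.mean()) ** 2)
    else:
        raise ValueError(f"unknown zscore mode: {zscore!r}")

    r2 = float(r2s.mean())
    r2a = adjusted_r2(r2, n, K)
    fit = EncodingFit(
        unit_id=unit_id, variant=variant, K=K, n_folds=n_folds,
        fold_assignment=assignment, betas=betas, r2_folds=r2s,
        beta=betas.mean(axis=0), r2=r2, r2_adj=r2a, seed=seed,
    )
    if reliability is not None:
        fit.reliability = float(reliability)
        _, _, fit.r2_norm, fit.r2_adj_norm = performance_metrics(
            r2, n, K, reliability
        )
    return fit


def fit_combined_model(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    y: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
    reliability: float | None = None,
    unit_id: str | None = None,
) -> EncodingFit:
    """PCR on the concatenated predictors of two feature banks.

    Fold assignment depends only on (n_stimuli, n_folds, seed), so passing
    the seeds used for the component fits keeps the three models'
    cross-validation identical -- the coherence the variance-partitioning
    identities rely on.  Redundant predictors are tolerated (least-squares
    falls back to the pseudoinverse solution).
    """
    Za, Zb = np.asarray(scores_a, float), np.asarray(scores_b, float)
    if Za.shape[0] != Zb.shape[0]:
        raise ValueError("score sets must share the stimulus ordering")
    return fit_pcr_cv(
        np.hstack([Za, Zb]), y, n_folds=n_folds, seed=seed,
        reliability=reliability, unit_id=unit_id, variant="combined",
    )


NULL_METHODS = ("label_shuffle_prefit", "test_label_shuffle", "beta_permutation")


def permutation_null(
    scores: np.ndarray,
    y: np.ndarray,
    method: str = "label_shuffle_prefit",
    n_perm: int = 1000,
    n_folds: int = 10,
    seed: int = 0,
    reliability: float = 1.0,
    permutations: list[np.ndarray] | None = None,
) -> NullDistribution:
    """Permutation null distribution of the reliability-normalized R2.

    * ``label_shuffle_prefit`` -- permute the stimulus labels of ``y`` and
      rerun the full cross-validated fit (the primary scheme);
    * ``test_label_shuffle`` -- fit with true labels, then permute only the
      held-out labels (within each test fold) before scoring;
    * ``beta_permutation`` -- fit with true labels, then permute the fitted
      beta entries across the K PCs before predicting.

    ``permutations`` overrides the random draws with explicit index arrays
    (stimulus permutations, or K-permutations for ``beta_permutation``) --
    useful for audits; an identity permutation reproduces the observed
    statistic exactly.
    """
    if method not in NULL_METHODS:
        raise ValueError(f"method must be one of {NULL_METHODS}, got {method!r}")
    Z = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, K = Z.shape
    rng = np.random.default_rng(seed)
    assignment = fold_split(n, n_folds, seed)
    yz = _zscore(y)
    if permutations is not None:
        n_perm = len(permutations)

    def draw(i: int, size: int) -> np.ndarray:
        if permutations is not None:
            return np.asarray(permutations[i])
        return rng.permutation(size)

    values = np.empty(n_perm)
    if method == "label_shuffle_prefit":
        for i in range(n_perm):
            _, r2s = _cv_fit(Z, yz[draw(i, n)], assignment, n_folds)
            values[i] = r2s.mean() / reliability
    else:
        betas, _ = _cv_fit(Z, yz, assignment, n_folds)
        for i in range(n_perm):
            r2s = np.empty(n_folds)
            if method == "test_label_shuffle":
                y_perm = yz[draw(i, n)] if permutations is not None else None
                for k in range(n_folds):
                    test = assignment == k
                    if y_perm is not None:
                        yt = y_perm[test]
                    else:
                        yt = yz[test][rng.permutation(int(test.sum()))]
                    yhat = Z[test] @ betas[k]
                    r2s[k] = 1.0 - np.sum((yt - yhat) ** 2) / np.sum(
                        (yt - yt.mean()) ** 2
                    )
            else:  # beta_permutation
                perm = draw(i, K)
                for k in range(n_folds):
                    test = assignment == k
                    yt = yz[test]
                    yhat = Z[test] @ betas[k][perm]
                    r2s[k] = 1.0 - np.sum((yt - yhat) ** 2) / np.sum(
                        (yt - yt.mean()) ** 2
                    )
            values[i] = r2s.mean() / reliability
    return NullDistribution(method=method, values=values, seed=seed)
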