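"""Model inversion: eigenposes, preferred-axis keypoints, and weights.

Because the encoding model is linear end to end (PCA then regression), a
fitted axis beta in PC space can be mapped back to keypoint space:

    t = P beta                      (d-vector, reshaped to 22 x 2 or 22 x 3)
    w_i = ||row i of T||            (contribution of keypoint i)
    e_{i,kappa} = mean + kappa * sigma_i * p_i          (eigenpose)
    a_kappa = mean + kappa * sum_i (sigma_i beta_i) sigma_i p_i
                                                    (pose along the axis)

Keypoint weights are given permutation p-values (stimulus labels shuffled,
model refitted, weights recomputed) with Benjamini-Hochberg correction
across the 22 keypoints; non-significant weights are zeroed for display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .encoding_model import _cv_fit, _zscore, fold_split


def eigenpose(basis, i: int, kappa: float) -> np.ndarray:
    """Pose kappa standard deviations along component ``i`` (0-based).

    Returns the keypoint configuration mean + kappa * sigma_i * p_i,
    reshaped to (22, 2) or (22, 3) per the basis's column layout.
    """
    if not 0 <= i < basis.K:
        raise IndexError(f"component index {i} out of range [0, {basis.K})")
    vec = basis.mean + kappa * basis.sds[i] * basis.components[:, i]
    return vec.reshape(22, -1)


def axis_to_keypoints(basis, beta: np.ndarray) -> np.ndarray:
    """Map a preferred axis to keypoint space: T = reshape(P beta, 22 x dims)."""
    t = basis.components @ np.asarray(beta, dtype=float)
    return t.reshape(22, -1)


def keypoint_weights(T: np.ndarray) -> np.ndarray:
    """Keypoint contributions: the row-wise magnitudes of T (22 values)."""
    return np.linalg.norm(np.asarray(T, dtype=float), axis=1)


def pose_along_axis(basis, beta: np.ndarray, kappa: float) -> np.ndarray:
    """Preferred pose kappa standard deviations along the fitted axis.

    a_kappa = mean + kappa * sum_i b_i sigma_i p_i with b_i = sigma_i beta_i
    (the betas rescaled from score space to coordinate standard deviations).
    """
    beta = np.asarray(beta, dtype=float)
    step = basis.components @ (basis.sds**2 * beta)
    return (basis.mean + kappa * step).reshape(22, -1)


def weight_significance(
    scores: np.ndarray,
    y: np.ndarray,
    basis,
    n_perm: int = 1000,
    alpha: float = 0.05,
    n_folds: int = 10,
    seed: int = 0,
    refit: str = "cv",
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation significance of the 22 keypoint weights.

    Shuffles the stimulus labels, refits the model (full cross-validation by
    default; ``refit="full"`` uses a single full-data least-squares fit as a
    cheaper null), and recomputes the weights.  One-sided p per keypoint =
    fraction of null weights >= the observed weight; Benjamini-Hochberg FDR
    across the 22 keypoints at ``alpha``.  Returns (p_values, significant).
    """
    if n_perm < 20:
        import warnings

        warnings.warn(
            f"n_perm={n_perm} gives a p-value resolution of only 1/{n_perm}",
            RuntimeWarning,
        )
    Z = np.asarray(scores, dtype=float)
    yz = _zscore(np.asarray(y, dtype=float).ravel())
    n = yz.size
    rng = np.random.default_rng(seed)
    assignment = fold_split(n, n_folds, seed)

    def fit_weights(target: np.ndarray) -> np.ndarray:
        if refit == "cv":
            betas, _ = _cv_fit(Z, target, assignment, n_folds)
            beta = betas.mean(axis=0)
        elif refit == "full":
            beta, *_ = np.linalg.lstsq(Z, target, rcond=None)
        else:
            raise ValueError(f"unknown refit mode: {refit!r}")
        return keypoint_weights(axis_to_keypoints(basis, beta))

    observed = fit_weights(yz)
    null_ge = np.zeros(22)
    for _ in range(n_perm):
        null_ge += fit_weights(yz[rng.permutation(n)]) >= observed
    pvals = null_ge / n_perm
    significant = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    return pvals, significant


@dataclass
class AxisVisualization:
    """Everything needed to draw a unit's preferred axis.

    ``weights`` are the raw keypoint magnitudes; ``weights_display`` are
    zeroed where not significant and then max-normalized (all-zero if no
    keypoint survives the FDR screen).  ``poses`` maps each kappa on the
    grid to the (22 x dims) pose along the axis.
    """

    unit_id: str | None
    T: np.ndarray
    weights: np.ndarray
    weights_display: np.ndarray
    pvals: np.ndarray | None
    significant: np.ndarray | None
    poses: dict[float, np.ndarray]
    kappas: tuple[float, ...]


def visualize_axis(
    basis,
    beta: np.ndarray,
    scores: np.ndarray | None = None,
    y: np.ndarray | None = None,
    kappas: tuple[float, ...] = (-3, -2, -1, 0, 1, 2, 3),
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    unit_id: str | None = None,
    refit: str = "cv",
) -> AxisVisualization:
    """Bundle the inversion products of one fitted axis.

    With ``scores`` and ``y`` given, keypoint weights carry permutation
    significance and the display weights zero out non-significant
    keypoints before max-normalization; otherwise all weights are kept.
    """
    T = axis_to_keypoints(basis, beta)
    w = keypoint_weights(T)
    pvals = significant = None
    display = w.copy()
    if scores is not None and y is not None:
        pvals, significant = weight_significance(
            scores, y, basis, n_perm=n_perm, alpha=alpha, seed=seed, refit=refit
        )
        display = np.where(significant, w, 0.0)
    if display.max() > 0:
        display = display / display.max()
    return AxisVisualization(
        unit_id=unit_id, T=T, weights=w, weights_display=display,
        pvals=pvals, significant=significant,
        poses={float(k): pose_along_axis(basis, beta, k) for k in kappas},
        kappas=tuple(float(k) for k in kappas),
    )


def plot_stick_figure(pose: np.ndarray, weights: np.ndarray | None = None, ax=None):
    """Render a (22 x 2/3) pose as a stick figure (x-y plane), weight-colored.

    Returns the matplotlib axes.  Import is deferred so headless use of the
    library never touches a plotting backend.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    from . import skeleton as sk

    if ax is None:
        _, ax = plt.subplots(figsize=(3, 3))
    xy = np.asarray(pose)[:, :2]
    for a, b in sk.BONES:
        ia, ib = sk.keypoint_index(a), sk.keypoint_index(b)
        ax.plot(xy[[ia, ib], 0], xy[[ia, ib], 1], color="0.6", lw=1.5, zorder=1)
    c = weights if weights is not None else np.zeros(len(xy))
    sc = ax.scatter(xy[:, 0], xy[:, 1], c=c, cmap="viridis", vmin=0.0, s=25, zorder=2)
    ax.invert_yaxis()  # image convention: y increases downward
    ax.set_aspect("equal")
    ax.set_xticks([])
    ax.set_yticks([])
    if weights is not None:
        plt.colorbar(sc, ax=ax, shrink=0.8, label="keypoint weight")
    return ax
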