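"""View Invariance Index (VII): viewpoint tolerance of a fitted axis.

The model's response to every stimulus is its distance along the preferred
axis, yhat = (X - mean) P beta.  For the (pose, camera elevation)
combination containing the maximum response, the observed range r_o of the
8 azimuth responses is compared with the ranges of random 8-value samples
that also contain the maximum (7 values drawn from the 712 stimuli outside
the best combination, plus yhat_max):

    Z_o = (r_o - mu_null) / sigma_null,        VII = -Z_o

A view-tolerant axis keeps its 8 views' responses tight (small r_o), giving
a large positive VII; a viewpoint-dominated axis spans the extremes across
views, giving a negative VII.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class VIIResult:
    """The observed range, its resampling null, and the index itself."""

    unit_id: str | None
    y_hat: np.ndarray
    best_pose: int
    best_elevation: float
    observed_range: float
    null_ranges: np.ndarray
    null_mean: float
    null_sd: float
    z_observed: float
    vii: float
    seed: int | None


def predict_model_responses(X, basis, beta: np.ndarray) -> np.ndarray:
    """Model responses (distances along the axis): (X - mean) P beta."""
    A = np.asarray(X.X if hasattr(X, "X") else X, dtype=float)
    return (A - basis.mean) @ (basis.components @ np.asarray(beta, dtype=float))


def compute_vii(
    y_hat: np.ndarray,
    stimulus_index: pd.DataFrame,
    n_resamples: int = 1000,
    seed: int = 0,
    unit_id: str | None = None,
) -> VIIResult:
    """View Invariance Index of a vector of model responses.

    ``stimulus_index`` must carry ``pose_id``, ``azimuth_deg`` and
    ``elevation_deg`` aligned with ``y_hat``; every (pose, elevation)
    combination must have a complete azimuth grid.  The maximum response is
    located (ties broken by lowest stimulus index); the null excludes all
    views of the best combination from the resampling pool and samples
    without replacement within a draw.
    """
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    pose = stimulus_index["pose_id"].to_numpy()
    elev = stimulus_index["elevation_deg"].to_numpy()
    if y_hat.size != pose.size:
        raise ValueError("y_hat and stimulus_index must be aligned")

    sizes = pd.Series(range(y_hat.size)).groupby([pose, elev]).size()
    if sizes.nunique() != 1:
        raise ValueError("incomplete azimuth grid for some (pose, elevation)")
    n_views = int(sizes.iloc[0])

    i_max = int(np.argmax(y_hat))  # argmax: lowest index wins ties
    best = (pose == pose[i_max]) & (elev == elev[i_max])
    group = y_hat[best]
    r_o = float(group.max() - group.min())

    pool = y_hat[~best]
    rng = np.random.default_rng(seed)
    null = np.empty(n_resamples)
    y_max = y_hat[i_max]
    for i in range(n_resamples):
        draw = rng.choice(pool, size=n_views - 1, replace=False)
        null[i] = max(draw.max(), y_max) - min(draw.min(), y_max)
    mu, sd = float(null.mean()), float(null.std())
    if sd == 0:
        raise FloatingPointError("degenerate null: zero variance in resampled ranges")
    z_o = (r_o - mu) / sd
    return VIIResult(
        unit_id=unit_id, y_hat=y_hat, best_pose=int(pose[i_max]),
        best_elevation=float(elev[i_max]), observed_range=r_o,
        null_ranges=null, null_mean=mu, null_sd=sd,
        z_observed=float(z_o), vii=float(-z_o), seed=seed,
    )
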