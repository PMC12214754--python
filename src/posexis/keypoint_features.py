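"""Keypoint data matrices, the pixel control matrix, and their PCA bases.

A data matrix stacks one stimulus per row and one scaled coordinate per
column (x1, y1[, z1], x2, ...; coordinates divided by the image size so all
values lie in [0, 1]).  Five variants encode different viewpoint hypotheses:

* ``2D`` / ``3D_VD`` -- view-dependent image-plane (x, y) or camera-aligned
  (x, y, z) coordinates of each rendered stimulus;
* ``2D_VF`` / ``3D_VF`` -- "view-flipped": the rows of mirror-symmetric
  azimuths (315/270/225 deg) are replaced by those of their partners
  (45/90/135 deg), so mirrored views share one representation;
* ``3D_VI`` -- "view-invariant": all azimuths of a pose share the 0-deg row
  of that pose and camera elevation.

PCA on a matrix yields the low-dimensional basis whose scores serve as
regression predictors downstream.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

VARIANTS = ("2D", "3D_VD", "2D_VF", "3D_VF", "3D_VI")
_BASE_OF = {"2D": "2D", "3D_VD": "3D_VD", "2D_VF": "2D", "3D_VF": "3D_VD",
            "3D_VI": "3D_VD"}

#: default view-flip replacement: late azimuths take their mirror partners' rows
FLIP_MAP = {315.0: 45.0, 270.0: 90.0, 225.0: 135.0}


@dataclass
class KeypointDataMatrix:
    """Stimuli x coordinate-columns matrix with its stimulus metadata.

    ``index`` carries (stimulus_index, pose_id, pose_class, azimuth_deg,
    elevation_deg) aligned with the rows of ``X``.
    """

    X: np.ndarray
    variant: str
    index: pd.DataFrame
    image_size: int
    n_keypoints: int = 22

    @property
    def n_stimuli(self) -> int:
        return self.X.shape[0]

    @property
    def dims(self) -> int:
        """Coordinates per keypoint: 2 for 2D variants, 3 for 3D variants."""
        return self.X.shape[1] // self.n_keypoints

    @property
    def column_layout(self) -> list[str]:
        axes = "xy" if self.dims == 2 else "xyz"
        return [f"{ax}{k + 1}" for k in range(self.n_keypoints) for ax in axes]

    def to_csv(self, path, header_path=None) -> None:
        pd.DataFrame(self.X, columns=self.column_layout).join(
            self.index.reset_index(drop=True)
        ).to_csv(path, index=False)
        if header_path is not None:
            with open(header_path, "w") as fh:
                json.dump(
                    {"variant": self.variant, "column_layout": self.column_layout,
                     "image_size": self.image_size,
                     "n_keypoints": self.n_keypoints}, fh, indent=1,
                )


def build_data_matrix(pose_set, variant: str = "2D") -> KeypointDataMatrix:
    """Assemble the data matrix of a pose set for one model variant.

    Rows follow stimulus order; coordinates are divided by the image size
    (z included, read literally as "each coordinate value").  View-flipped
    and view-invariant variants are derived from the base matrix by row
    replacement, never by mirroring coordinates.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    coords = pose_set.coords  # (n, 22, 3)
    if not np.all(np.isfinite(coords)):
        raise ValueError("incomplete input: non-finite keypoint coordinates")
    dims = 2 if _BASE_OF[variant] == "2D" else 3
    X = coords[:, :, :dims].reshape(coords.shape[0], -1) / float(pose_set.image_size)
    mat = KeypointDataMatrix(
        X=X, variant=_BASE_OF[variant], index=pose_set.index,
        image_size=pose_set.image_size, n_keypoints=pose_set.n_keypoints,
    )
    if variant.endswith("_VF"):
        mat = apply_view_flip(mat)
    elif variant == "3D_VI":
        mat = apply_view_invariance(mat)
    return mat


def _row_lookup(index: pd.DataFrame) -> dict:
    """(pose_id, elevation, azimuth) -> row position."""
    return {
        (int(p), float(e), float(a)): i
        for i, (p, e, a) in enumerate(
            zip(index["pose_id"], index["elevation_deg"], index["azimuth_deg"])
        )
    }


def apply_view_flip(mat: KeypointDataMatrix, reverse: bool = False) -> KeypointDataMatrix:
    """Equate mirror-symmetric azimuths by row replacement.

    By default rows at 315/270/225 deg take the values of 45/90/135 deg
    (same pose, same elevation); 0 and 180 deg are untouched.  ``reverse``
    applies the opposite replacement direction (the control ordering).
    Idempotent.
    """
    if mat.variant.endswith("_VF") or mat.variant == "3D_VI":
        return replace(mat, X=mat.X.copy())
    flip = {v: k for k, v in FLIP_MAP.items()} if reverse else FLIP_MAP
    lookup = _row_lookup(mat.index)
    X = mat.X.copy()
    for i, (p, e, a) in enumerate(
        zip(mat.index["pose_id"], mat.index["elevation_deg"], mat.index["azimuth_deg"])
    ):
        src_az = flip.get(float(a))
        if src_az is None:
            continue
        key = (int(p), float(e), src_az)
        if key not in lookup:
            raise ValueError(f"incomplete azimuth grid: missing {key}")
        X[i] = mat.X[lookup[key]]
    return replace(mat, X=X, variant=f"{mat.variant.split('_')[0]}_VF"
                   if mat.variant == "2D" else "3D_VF")


def apply_view_invariance(mat: KeypointDataMatrix) -> KeypointDataMatrix:
    """Give all azimuths of a (pose, elevation) the 0-deg reference row."""
    if mat.variant == "3D_VI":
        return replace(mat, X=mat.X.copy())
    lookup = _row_lookup(mat.index)
    X = mat.X.copy()
    for i, (p, e, a) in enumerate(
        zip(mat.index["pose_id"], mat.index["elevation_deg"], mat.index["azimuth_deg"])
    ):
        key = (int(p), float(e), 0.0)
        if key not in lookup:
            raise ValueError(f"incomplete azimuth grid: missing {key}")
        X[i] = mat.X[lookup[key]]
    return replace(mat, X=X, variant="3D_VI")


def flip_scores(
    Z: np.ndarray, index: pd.DataFrame, reverse: bool = False, recenter: bool = True
) -> np.ndarray:
    """Equate PC *scores* of mirrored views (the alternative VF construction).

    Applies the same row replacement as :func:`apply_view_flip`, but to a
    score matrix computed in the unflipped basis.  Keeping the original PC
    space while equating mirrored views' scores is the second construction
    of the view-flipped model; it ranks units' predictive performances
    near-identically to PCA on flipped coordinates.  Row replacement shifts
    the column means away from zero, so the columns are recentred by
    default -- score predictors must stay zero-mean for the no-intercept
    regression downstream.
    """
    flip = {v: k for k, v in FLIP_MAP.items()} if reverse else FLIP_MAP
    lookup = _row_lookup(index)
    out = np.asarray(Z, dtype=float).copy()
    for i, (p, e, a) in enumerate(
        zip(index["pose_id"], index["elevation_deg"], index["azimuth_deg"])
    ):
        src_az = flip.get(float(a))
        if src_az is None:
            continue
        out[i] = Z[lookup[(int(p), float(e), src_az)]]
    if recenter:
        out -= out.mean(axis=0)
    return out


def build_pixel_matrix(silhouettes) -> np.ndarray:
    """Vectorize silhouette pixels into a (stimuli x grid*grid) matrix."""
    return silhouettes.pixels


@dataclass
class PCBasis:
    """A PCA basis: mean, orthonormal components, and score spreads.

    ``components`` is d x K with orthonormal columns; ``sds[i]`` is the
    standard deviation of the training scores along component i (the square
    root of the eigenvalue).
    """

    mean: np.ndarray
    components: np.ndarray
    sds: np.ndarray
    explained_variance_ratio: np.ndarray
    n_samples: int

    @property
    def K(self) -> int:
        return self.components.shape[1]

    @property
    def d(self) -> int:
        return self.components.shape[0]

    def project(self, X: np.ndarray) -> np.ndarray:
        """Scores Z = (X - mean) @ components."""
        return (np.asarray(X, dtype=float) - self.mean) @ self.components

    def reconstruct(self, Z: np.ndarray) -> np.ndarray:
        return self.mean + np.asarray(Z, dtype=float) @ self.components.T

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"mean": self.mean.tolist(), "components": self.components.tolist(),
                 "sds": self.sds.tolist(),
                 "explained_variance_ratio": self.explained_variance_ratio.tolist(),
                 "n_samples": self.n_samples}, fh,
            )

    @classmethod
    def from_json(cls, path) -> "PCBasis":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            mean=np.array(d["mean"]), components=np.array(d["components"]),
            sds=np.array(d["sds"]),
            explained_variance_ratio=np.array(d["explained_variance_ratio"]),
            n_samples=int(d["n_samples"]),
        )


def fit_pca(X, n_components: int = 10) -> PCBasis:
    """PCA of a (centered-by-column) data matrix with a fixed sign convention.

    Accepts a raw array or a :class:`KeypointDataMatrix`.  The sign of each
    component is fixed by making its largest-magnitude loading positive, so
    bases (and everything derived from them) are reproducible across runs.
    If the matrix rank is below ``n_components``, the available components
    are returned with a warning.
    """
    A = np.asarray(X.X if hasattr(X, "X") else X, dtype=float)
    n, d = A.shape
    if n_components > min(n - 1, d):
        raise ValueError(
            f"n_components={n_components} exceeds min(rows-1, cols)={min(n - 1, d)}"
        )
    mean = A.mean(axis=0)
    centered = A - mean
    # thin SVD; deterministic for a fixed input
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    var = S**2 / (n - 1)
    total_var = centered.var(axis=0, ddof=1).sum()
    rank = int(np.sum(S > S[0] * 1e-10)) if S.size else 0
    keep = n_components
    if rank < n_components:
        warnings.warn(
            f"rank deficiency: only {rank} informative components available "
            f"(requested {n_components})", RuntimeWarning,
        )
        keep = rank
    comps = Vt[:keep].T.copy()
    # sign convention: largest-magnitude loading of each component positive
    for j in range(keep):
        i_max = np.argmax(np.abs(comps[:, j]))
        if comps[i_max, j] < 0:
            comps[:, j] *= -1.0
    return PCBasis(
        mean=mean, components=comps, sds=np.sqrt(var[:keep]),
        explained_variance_ratio=var[:keep] / total_var, n_samples=n,
    )
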