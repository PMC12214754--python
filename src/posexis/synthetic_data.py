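"""Synthetic stimulus set and simulated spiking units.

Emulates the two inputs of the analysis so every downstream stage is testable
without recorded data:

* a stimulus grid of 45 natural poses of an articulated 22-keypoint skeleton,
  each rendered from 16 viewpoints (8 azimuths x 2 camera elevations) by
  orthographic projection, plus silhouette versions of the images;
* spiking units whose mean response is a linear function of the stimulus
  position along a ground-truth axis in keypoint principal-component space,
  with Poisson trial noise calibrated to a target split-half reliability.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import skeleton as sk
from .unit_selection import split_half_reliability_matrix

RESPONSE_WINDOW_S = 0.2   #: pose-test response window (200 ms)
BASELINE_WINDOW_S = 0.1   #: pose-test baseline window (100 ms)
CATEGORY_RESPONSE_WINDOW_S = 1.0
CATEGORY_BASELINE_WINDOW_S = 0.2


@dataclass
class StimulusPose:
    """One rendered stimulus: a pose seen from one viewpoint.

    ``coords`` is (22, 3) in pixels: x, y in the image plane (origin top-left,
    y increasing downward) and z the signed distance from the frontal plane
    through the pelvis, in the same pixel units.
    """

    pose_id: int
    pose_class: int
    azimuth: float
    elevation: float
    coords: np.ndarray


@dataclass
class PoseSet:
    """The full stimulus grid: ``n_poses * n_views`` rendered skeletons."""

    stimuli: list[StimulusPose]
    keypoint_labels: tuple[str, ...] = sk.KEYPOINT_LABELS
    image_size: int = 350
    global_scale: float = float("nan")

    @property
    def n_keypoints(self) -> int:
        return len(self.keypoint_labels)

    @property
    def n_stimuli(self) -> int:
        return len(self.stimuli)

    @property
    def coords(self) -> np.ndarray:
        """(n_stimuli, 22, 3) pixel coordinates in stimulus order."""
        return np.stack([s.coords for s in self.stimuli])

    @property
    def index(self) -> pd.DataFrame:
        """Stimulus metadata: pose_id, pose_class, azimuth, elevation."""
        return pd.DataFrame(
            {
                "stimulus_index": np.arange(self.n_stimuli),
                "pose_id": [s.pose_id for s in self.stimuli],
                "pose_class": [s.pose_class for s in self.stimuli],
                "azimuth_deg": [s.azimuth for s in self.stimuli],
                "elevation_deg": [s.elevation for s in self.stimuli],
            }
        )

    def to_csv(self, path) -> None:
        """Write the long-format keypoint table (one row per keypoint)."""
        rows = []
        for i, s in enumerate(self.stimuli):
            for k, lab in enumerate(self.keypoint_labels):
                rows.append(
                    (i, s.pose_id, s.pose_class, s.azimuth, s.elevation,
                     lab, s.coords[k, 0], s.coords[k, 1], s.coords[k, 2])
                )
        pd.DataFrame(
            rows,
            columns=["stimulus_index", "pose_id", "pose_class", "azimuth_deg",
                     "elevation_deg", "keypoint_label", "x_px", "y_px", "z_px"],
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, image_size: int = 350) -> "PoseSet":
        df = pd.read_csv(path, float_precision="round_trip")
        labels = tuple(df["keypoint_label"].unique())
        stimuli = []
        for _, grp in df.groupby("stimulus_index", sort=True):
            grp = grp.set_index("keypoint_label").loc[list(labels)]
            first = grp.iloc[0]
            stimuli.append(
                StimulusPose(
                    pose_id=int(first["pose_id"]),
                    pose_class=int(first["pose_class"]),
                    azimuth=float(first["azimuth_deg"]),
                    elevation=float(first["elevation_deg"]),
                    coords=grp[["x_px", "y_px", "z_px"]].to_numpy(float),
                )
            )
        return cls(stimuli=stimuli, keypoint_labels=labels, image_size=image_size)


@dataclass
class SilhouetteStack:
    """Binary silhouettes of the stimuli, downsampled to ``grid x grid``."""

    images: np.ndarray  # (n_stimuli, grid, grid) uint8 in {0, 1}
    grid: int
    image_size: int

    @property
    def pixels(self) -> np.ndarray:
        """(n_stimuli, grid*grid) flattened pixel values."""
        return self.images.reshape(self.images.shape[0], -1).astype(float)


@dataclass
class UnitRecording:
    """Trial-level window firing rates of one (simulated) unit."""

    unit_id: str
    response_rates: np.ndarray  # (n_trials, n_stimuli), spikes/s
    baseline_rates: np.ndarray  # (n_trials, n_stimuli)
    category_rates: dict | None = None
    ground_truth: dict | None = None

    @property
    def n_trials(self) -> int:
        return self.response_rates.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.response_rates.shape[1]

    @property
    def mean_response(self) -> np.ndarray:
        """Across-trial mean response-window rate per stimulus."""
        return self.response_rates.mean(axis=0)


def generate_pose_set(
    n_poses: int = 45,
    n_views: int = 16,
    image_size: int = 350,
    seed: int = 0,
) -> PoseSet:
    """Render the stimulus grid of posed skeletons.

    Poses are assigned round-robin to the 9 behavioural classes (45 poses =
    9 classes x 5 exemplars), each exemplar drawn from its class's
    joint-angle distribution.  Each pose is rendered at ``n_views // 2``
    azimuths (uniform steps) for camera elevations 0 and 45 degrees; for the
    hanging class, the elevated cameras are displaced below the horizontal
    plane, looking up at 45 degrees.  A single global scale maps the maximum
    horizontal/vertical extent (about the pelvis aim point) across all
    stimuli onto the image size, so every x, y lies in [0, image_size].
    """
    if n_poses < 1:
        raise ValueError(f"n_poses must be >= 1, got {n_poses}")
    if n_views < 2 or n_views % 2:
        raise ValueError(f"n_views must be a positive multiple of 2, got {n_views}")

    rng = np.random.default_rng(seed)
    n_az = n_views // 2
    azimuths = [i * 360.0 / n_az for i in range(n_az)]
    elevations = (0.0, 45.0)

    meta, raw = [], []
    for pose_id in range(1, n_poses + 1):
        pose_class = (pose_id - 1) % 9 + 1
        params = sk.class_parameters(pose_class, rng)
        body = sk.build_skeleton(params)
        for elev in elevations:
            cam_elev = elev
            if pose_class == sk.HANGING_CLASS and elev != 0.0:
                cam_elev = -elev  # cameras below the horizontal, looking up
            for az in azimuths:
                raw.append(sk.project_skeleton(body, az, cam_elev))
                meta.append((pose_id, pose_class, az, elev))

    raw = np.stack(raw)  # (n_stim, 22, 3), model units, y up
    half_extent = np.abs(raw[:, :, :2]).max()
    if half_extent <= 0:
        raise RuntimeError("degenerate skeleton: all keypoints coincide with the pelvis")
    scale = image_size / (2.0 * half_extent)

    stimuli = []
    c = image_size / 2.0
    for (pose_id, pose_class, az, elev), xyz in zip(meta, raw):
        coords = np.column_stack(
            [c + scale * xyz[:, 0], c - scale * xyz[:, 1], scale * xyz[:, 2]]
        )
        stimuli.append(StimulusPose(pose_id, pose_class, az, elev, coords))
    return PoseSet(stimuli=stimuli, image_size=image_size, global_scale=scale)


def _disk_offsets(radius: int) -> np.ndarray:
    r = np.arange(-radius, radius + 1)
    dy, dx = np.meshgrid(r, r, indexing="ij")
    keep = dy**2 + dx**2 <= radius**2
    return np.column_stack([dy[keep], dx[keep]])


def render_silhouettes(
    pose_set: PoseSet, grid: int = 25, bone_radius: int | None = None
) -> SilhouetteStack:
    """Rasterize skeleton bones as thick segments and block-max downsample.

    Bones are drawn on the full-resolution canvas as line segments of
    half-width ``bone_radius`` pixels (default: ~1.5% of the image size),
    then reduced to a ``grid x grid`` binary image by taking the maximum
    over pixel blocks.  Points falling off the canvas are clipped away.
    """
    if grid < 8:
        raise ValueError(f"grid must be >= 8, got {grid}")
    size = pose_set.image_size
    if bone_radius is None:
        bone_radius = max(2, round(0.015 * size))
    block = math.ceil(size / grid)
    padded = block * grid
    offsets = _disk_offsets(bone_radius)
    bone_idx = [(sk.keypoint_index(a), sk.keypoint_index(b)) for a, b in sk.BONES]

    images = np.zeros((pose_set.n_stimuli, grid, grid), dtype=np.uint8)
    for i, stim in enumerate(pose_set.stimuli):
        canvas = np.zeros((padded, padded), dtype=bool)
        pts = []
        for a, b in bone_idx:
            p, q = stim.coords[a, :2], stim.coords[b, :2]
            n = max(2, int(np.hypot(*(q - p)) / 1.5) + 1)
            t = np.linspace(0.0, 1.0, n)[:, None]
            pts.append(p + t * (q - p))
        pts = np.round(np.concatenate(pts)).astype(int)
        stamped = pts[:, None, :] + offsets[None, :, ::-1]  # (pts, off, [x, y])
        stamped = stamped.reshape(-1, 2)
        ok = (
            (stamped[:, 0] >= 0) & (stamped[:, 0] < padded)
            & (stamped[:, 1] >= 0) & (stamped[:, 1] < padded)
        )
        stamped = stamped[ok]
        canvas[stamped[:, 1], stamped[:, 0]] = True
        images[i] = (
            canvas.reshape(grid, block, grid, block).max(axis=(1, 3)).astype(np.uint8)
        )
    return SilhouetteStack(images=images, grid=grid, image_size=size)


def _draw_trials(
    mean_rates: np.ndarray,
    n_trials: int,
    window_s: float,
    noise: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Trial rates (..., n_trials, n_stimuli) around per-stimulus means."""
    shape = (n_trials,) + mean_rates.shape
    if noise == "poisson":
        counts = rng.poisson(np.broadcast_to(mean_rates * window_s, shape))
        return counts / window_s
    if noise == "gaussian":
        sd = np.sqrt(np.maximum(mean_rates, 0.0) / window_s)
        return np.maximum(mean_rates + sd * rng.standard_normal(shape), 0.0)
    if noise == "none":
        return np.broadcast_to(mean_rates, shape).copy()
    raise ValueError(f"unknown noise model: {noise!r}")


def _mean_rates(
    pc_scores: np.ndarray, betas: np.ndarray, gain: float, baseline: float
) -> np.ndarray:
    """Rectified linear rates, (n_units, n_stimuli)."""
    return np.maximum(baseline + gain * betas @ pc_scores.T, 0.0)


def _median_reliability(
    pc_scores, betas, gain, baseline, n_trials, noise, seed, n_splits
) -> float:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2**20 + 7]))
    means = _mean_rates(pc_scores, betas, gain, baseline)
    trials = _draw_trials(means, n_trials, RESPONSE_WINDOW_S, noise, rng)
    trials = np.moveaxis(trials, 0, 1)  # (units, trials, stimuli)
    rel = split_half_reliability_matrix(
        trials, n_splits=n_splits, rng=np.random.default_rng(
            np.random.SeedSequence([seed, 2**20 + 11]))
    )
    return float(np.median(rel))


def calibrate_gain(
    pc_scores: np.ndarray,
    betas: np.ndarray,
    target_reliability: float,
    n_trials: int,
    baseline: float,
    noise: str = "poisson",
    seed: int = 0,
    tol: float = 0.02,
    n_splits: int = 20,
    bracket: tuple[float, float] = (1e-3, 1e5),
    max_iter: int = 40,
) -> float:
    """Bisection on log-gain so the population's median split-half
    reliability matches ``target_reliability``.

    The trial noise within the search uses a fixed stream (common random
    numbers), making the reliability-vs-gain curve effectively monotone.
    """
    if not 0.0 < target_reliability < 1.0:
        raise ValueError(f"target_reliability must be in (0, 1), got {target_reliability}")

    def f(gain: float) -> float:
        return _median_reliability(
            pc_scores, betas, gain, baseline, n_trials, noise, seed, n_splits
        )

    lo, hi = bracket
    f_lo, f_hi = f(lo), f(hi)
    if not (f_lo < target_reliability < f_hi):
        raise RuntimeError(
            "reliability calibration failed to bracket the target: "
            f"f({lo:g})={f_lo:.3f}, f({hi:g})={f_hi:.3f}, target={target_reliability}"
        )
    for _ in range(max_iter):
        mid = math.sqrt(lo * hi)
        f_mid = f(mid)
        if abs(f_mid - target_reliability) <= tol:
            return mid
        if f_mid < target_reliability:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def simulate_encoding_units(
    pc_scores: np.ndarray,
    n_units: int,
    target_reliability: float | None = 0.7,
    n_trials: int = 6,
    gain: float | None = None,
    baseline: float = 10.0,
    noise: str = "poisson",
    variant: str | None = None,
    seed: int = 0,
) -> list[UnitRecording]:
    """Simulate units tuned along random axes in keypoint-PC space.

    Each unit's ground-truth axis ``beta_true`` is drawn uniformly on the
    unit sphere of the PC space spanned by ``pc_scores`` (stimuli x K).  The
    mean response is ``rectify(baseline + gain * Z beta_true)`` and trials
    are drawn from the chosen noise model over the 200 ms response window.
    With ``gain=None`` the gain is calibrated by bisection so the median
    split-half reliability of the population hits ``target_reliability``
    (within +/- 0.05; internal tolerance 0.02).
    """
    if baseline < 0:
        raise ValueError("baseline must be >= 0")
    rng = np.random.default_rng(seed)
    betas = rng.standard_normal((n_units, pc_scores.shape[1]))
    betas /= np.linalg.norm(betas, axis=1, keepdims=True)

    if gain is None:
        gain = calibrate_gain(
            pc_scores, betas, target_reliability, n_trials, baseline,
            noise=noise, seed=seed,
        )

    means = _mean_rates(pc_scores, betas, gain, baseline)
    resp = _draw_trials(means, n_trials, RESPONSE_WINDOW_S, noise, rng)
    resp = np.moveaxis(resp, 0, 1)  # (units, trials, stimuli)
    base = _draw_trials(
        np.full_like(means, baseline), n_trials, BASELINE_WINDOW_S, noise, rng
    )
    base = np.moveaxis(base, 0, 1)

    units = []
    for u in range(n_units):
        units.append(
            UnitRecording(
                unit_id=f"sim{seed}_{u:04d}",
                response_rates=resp[u],
                baseline_rates=base[u],
                ground_truth={
                    "variant": variant,
                    "beta_true": betas[u].tolist(),
                    "gain": float(gain),
                    "baseline": float(baseline),
                    "noise": noise,
                    "n_trials": int(n_trials),
                    "target_reliability": target_reliability,
                    "seed": int(seed),
                },
            )
        )
    return units


def simulate_category_responses(
    body_gain: float,
    nonbody_gain: float,
    n_trials: int = 5,
    baseline: float = 5.0,
    noise: str = "poisson",
    seed: int = 0,
) -> dict:
    """Simulate the body/face/object category test (20 movies per category).

    Mean *net* rates are ``body_gain`` for bodies and ``nonbody_gain`` for
    faces and objects; trial noise is Poisson over the category-test windows
    (1 s response, 200 ms baseline).  Returns a dict with ``response_rates``
    and ``baseline_rates`` (n_trials x 60) and ``labels``.
    """
    if body_gain < 0 or nonbody_gain < 0:
        raise ValueError("gains must be >= 0")
    rng = np.random.default_rng(seed)
    labels = np.array(["body"] * 20 + ["face"] * 20 + ["object"] * 20)
    means = baseline + np.where(labels == "body", body_gain, nonbody_gain)
    resp = _draw_trials(means, n_trials, CATEGORY_RESPONSE_WINDOW_S, noise, rng)
    base = _draw_trials(
        np.full(60, float(baseline)), n_trials, CATEGORY_BASELINE_WINDOW_S, noise, rng
    )
    return {"response_rates": resp, "baseline_rates": base, "labels": labels}


def surrogate_feature_matrix(
    source,
    n_features: int,
    nonlinearity: str = "relu",
    projection: str = "gaussian",
    seed: int = 0,
) -> np.ndarray:
    """Random-projection feature bank with the data-matrix interface.

    A stand-in for an image-computable feature bank (e.g. network-layer
    activations): seeded random projections of silhouette pixels (or of a
    keypoint data matrix) passed through a pointwise nonlinearity.  Returns
    a (stimuli x n_features) array usable wherever a data matrix is.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if isinstance(source, SilhouetteStack):
        base = source.pixels
    elif hasattr(source, "X"):
        base = np.asarray(source.X, dtype=float)
    else:
        base = np.asarray(source, dtype=float)

    if projection == "identity":
        if n_features != base.shape[1]:
            raise ValueError("identity projection requires n_features == source width")
        feats = base.copy()
    elif projection == "gaussian":
        rng = np.random.default_rng(seed)
        w = rng.standard_normal((base.shape[1], n_features)) / math.sqrt(base.shape[1])
        feats = base @ w
    else:
        raise ValueError(f"unknown projection: {projection!r}")

    if nonlinearity == "identity":
        return feats
    if nonlinearity == "relu":
        return np.maximum(feats, 0.0)
    if nonlinearity == "tanh":
        return np.tanh(feats)
    raise ValueError(f"unknown nonlinearity: {nonlinearity!r}")


def save_units_csv(units: list[UnitRecording], rates_path, ground_truth_path=None) -> None:
    """Write trial rates in long format (+ optional ground-truth JSON sidecar)."""
    if not units:
        pd.DataFrame(
            columns=["unit_id", "stimulus_index", "trial_index", "window", "rate_hz"]
        ).to_csv(rates_path, index=False)
        if ground_truth_path is not None:
            with open(ground_truth_path, "w") as fh:
                json.dump({}, fh)
        return
    frames = []
    for unit in units:
        n_t, n_s = unit.response_rates.shape
        tr, st = np.meshgrid(np.arange(n_t), np.arange(n_s), indexing="ij")
        for window, rates in (
            ("response", unit.response_rates), ("baseline", unit.baseline_rates)
        ):
            frames.append(
                pd.DataFrame(
                    {
                        "unit_id": unit.unit_id,
                        "stimulus_index": st.ravel(),
                        "trial_index": tr.ravel(),
                        "window": window,
                        "rate_hz": rates.ravel(),
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(rates_path, index=False)
    if ground_truth_path is not None:
        gt = {u.unit_id: u.ground_truth for u in units if u.ground_truth is not None}
        with open(ground_truth_path, "w") as fh:
            json.dump(gt, fh, indent=1)


def load_units_csv(rates_path, ground_truth_path=None) -> list[UnitRecording]:
    df = pd.read_csv(rates_path, float_precision="round_trip")
    gt = {}
    if ground_truth_path is not None:
        with open(ground_truth_path) as fh:
            gt = json.load(fh)
    units = []
    for unit_id, grp in df.groupby("unit_id", sort=True):
        mats = {}
        for window, sub in grp.groupby("window"):
            mats[window] = (
                sub.pivot(index="trial_index", columns="stimulus_index", values="rate_hz")
                .sort_index()
                .to_numpy(float)
            )
        units.append(
            UnitRecording(
                unit_id=str(unit_id),
                response_rates=mats["response"],
                baseline_rates=mats["baseline"],
                ground_truth=gt.get(str(unit_id)),
            )
        )
    return units
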