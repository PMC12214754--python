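"""End-to-end orchestration of the synthetic encoding-model analysis.

One config and one seed drive the full chain: simulate stimuli and units ->
screen units -> build the five data-matrix variants -> fit every variant per
unit -> invert axes -> view-invariance -> variance partitioning -> cluster
preferred axes -> decode pose.  Every stage writes its artifacts under the
output directory and registers them (with SHA-256 checksums) in a manifest,
so a rerun with an identical config is verifiably bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .axis_inversion import visualize_axis
from .encoding_model import fit_pcr_cv, fit_combined_model
from .keypoint_features import VARIANTS, build_data_matrix, fit_pca
from .population_analysis import cluster_axes, decode_poses, variance_partition
from .synthetic_data import (
    generate_pose_set,
    render_silhouettes,
    save_units_csv,
    simulate_category_responses,
    simulate_encoding_units,
    surrogate_feature_matrix,
)
from .unit_selection import SelectionThresholds, select_units, selection_frame
from .unit_selection import split_half_reliability_matrix

STAGES = (
    "simulate", "matrices", "select", "fit", "invert",
    "vii", "partition", "cluster", "decode",
)


@dataclass
class RunConfig:
    """Parameters of a pipeline run.  Defaults are the analysis's standard
    settings: 10 keypoint PCs, 50 feature-bank PCs, 10 folds, 1000
    permutations, and the default screening thresholds."""

    seed: int = 0
    out_dir: str = "posexis_run"
    # stimuli
    n_poses: int = 45
    n_views: int = 16
    image_size: int = 350
    silhouette_grid: int = 25
    # population
    n_units_per_variant: int = 10
    target_reliability: float = 0.7
    n_trials: int = 6
    baseline_rate: float = 10.0
    body_gain: float = 12.0
    nonbody_gain: float = 2.0
    # models
    n_pcs_keypoint: int = 10
    n_pcs_feature_bank: int = 50
    n_feature_bank: int = 500
    n_folds: int = 10
    n_perm: int = 1000
    vii_resamples: int = 1000
    r2_gate: float = 0.25
    cluster_variant: str = "2D"
    partition_variant: str = "2D"
    decode_resamples: int = 50
    decode_label_perms: int = 0
    decode_max_pseudotrials: int | None = None
    test_mode: bool = False

    def __post_init__(self):
        if self.test_mode:
            # reduced permutation/resample counts; formulas unchanged
            self.n_perm = min(self.n_perm, 50)
            self.vii_resamples = min(self.vii_resamples, 200)
            self.decode_resamples = min(self.decode_resamples, 5)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1000003 + STAGES.index(stage) + 1) % (2**31 - 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class Pipeline:
    """Lazily executed stage chain; each stage's products live on ``self``."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "version": __version__, "seed": config.seed,
            "config": asdict(config), "stages": {},
        }
        self._done: set[str] = set()

    # -- bookkeeping --------------------------------------------------------

    def _register(self, stage: str, paths: list[Path], summary: dict, t0: float):
        self.manifest["stages"][stage] = {
            "artifacts": {p.name: _sha256(p) for p in paths},
            "summary": summary,
            "wall_time_s": round(time.time() - t0, 3),
            "seed": self.config.stage_seed(stage),
        }
        self._done.add(stage)

    def run_through(self, stage: str) -> None:
        for s in STAGES[: STAGES.index(stage) + 1]:
            if s not in self._done:
                t0 = time.time()
                try:
                    getattr(self, f"_stage_{s}")(t0)
                except Exception as err:
                    raise RuntimeError(
                        f"pipeline stage '{s}' failed ({err}); rerun just this "
                        f"stage with: posexis {s} --config <config.yaml>"
                    ) from err

    def run_all(self) -> dict:
        self.run_through(STAGES[-1])
        path = self.out / "manifest.json"
        path.write_text(json.dumps(self.manifest, indent=1, sort_keys=True))
        return self.manifest

    # -- stages -------------------------------------------------------------

    def _stage_simulate(self, t0):
        cfg = self.config
        self.pose_set = generate_pose_set(
            cfg.n_poses, cfg.n_views, cfg.image_size, seed=cfg.stage_seed("simulate")
        )
        self.silhouettes = render_silhouettes(self.pose_set, cfg.silhouette_grid)
        kp = self.out / "keypoints.csv"
        self.pose_set.to_csv(kp)
        np.savetxt(
            self.out / "silhouettes.csv",
            self.silhouettes.pixels.astype(int), fmt="%d", delimiter=",",
        )
        self._register(
            "simulate", [kp, self.out / "silhouettes.csv"],
            {"n_stimuli": self.pose_set.n_stimuli,
             "global_scale": self.pose_set.global_scale}, t0,
        )

    def _stage_matrices(self, t0):
        cfg = self.config
        self.matrices, self.bases, self.scores = {}, {}, {}
        paths, widths = [], {}
        for variant in VARIANTS:
            mat = build_data_matrix(self.pose_set, variant)
            self.matrices[variant] = mat
            self.bases[variant] = fit_pca(mat, cfg.n_pcs_keypoint)
            self.scores[variant] = self.bases[variant].project(mat.X)
            p = self.out / f"matrix_{variant}.csv"
            mat.to_csv(p, header_path=self.out / f"matrix_{variant}.json")
            paths += [p, self.out / f"matrix_{variant}.json"]
            widths[variant] = mat.X.shape[1]
        self.feature_bank = surrogate_feature_matrix(
            self.silhouettes, cfg.n_feature_bank, seed=cfg.stage_seed("matrices")
        )
        self.fb_basis = fit_pca(self.feature_bank, cfg.n_pcs_feature_bank)
        self.fb_scores = self.fb_basis.project(self.feature_bank)
        self._register("matrices", paths, {"widths": widths}, t0)

    def _stage_select(self, t0):
        cfg = self.config
        seed = cfg.stage_seed("select")
        self.units, self.unit_variant = [], {}
        for vi, variant in enumerate(VARIANTS):
            if cfg.n_units_per_variant == 0:
                continue
            sims = simulate_encoding_units(
                self.scores[variant], cfg.n_units_per_variant,
                cfg.target_reliability, cfg.n_trials,
                baseline=cfg.baseline_rate, variant=variant, seed=seed + vi,
            )
            for ui, u in enumerate(sims):
                u.category_rates = simulate_category_responses(
                    cfg.body_gain, cfg.nonbody_gain, seed=seed + 101 * vi + ui
                )
                self.unit_variant[u.unit_id] = variant
            self.units += sims
        rates_csv = self.out / "trial_rates.csv"
        save_units_csv(self.units, rates_csv, self.out / "ground_truth.json")

        self.reports = select_units(self.units, SelectionThresholds(), seed=seed)
        sel_csv = self.out / "selection.csv"
        if self.reports:
            selection_frame(self.reports).to_csv(sel_csv, index=False)
        else:
            pd.DataFrame({"unit_id": []}).to_csv(sel_csv, index=False)
        self.selected = [
            u for u, r in zip(self.units, self.reports) if r.passed
        ]
        self.selected_reliability = {
            r.unit_id: r.reliability for r in self.reports if r.passed
        }
        self._register(
            "select", [rates_csv, self.out / "ground_truth.json", sel_csv],
            {"n_units": len(self.units), "n_selected": len(self.selected)}, t0,
        )

    def _stage_fit(self, t0):
        cfg = self.config
        seed = cfg.stage_seed("fit")
        self.fits: dict[str, dict] = {}
        rows = []
        for i, unit in enumerate(self.selected):
            rel = self.selected_reliability[unit.unit_id]
            y = unit.mean_response
            per_variant = {}
            for variant in VARIANTS:
                fit = fit_pcr_cv(
                    self.scores[variant], y, n_folds=cfg.n_folds,
                    seed=seed + i, reliability=rel,
                    unit_id=unit.unit_id, variant=variant,
                )
                per_variant[variant] = fit
                rows.append(
                    {"unit_id": unit.unit_id, "variant": variant,
                     "generative_variant": self.unit_variant[unit.unit_id],
                     "r2": fit.r2, "r2_adj": fit.r2_adj, "reliability": rel,
                     "r2_norm": fit.r2_norm, "r2_adj_norm": fit.r2_adj_norm}
                )
            self.fits[unit.unit_id] = per_variant
        fits_csv = self.out / "fits.csv"
        pd.DataFrame(rows).to_csv(fits_csv, index=False)
        self._register("fit", [fits_csv], {"n_fits": len(rows)}, t0)

    def _best_variant(self, unit_id: str) -> str:
        return max(VARIANTS, key=lambda v: self.fits[unit_id][v].r2_norm)

    def _stage_invert(self, t0):
        cfg = self.config
        seed = cfg.stage_seed("invert")
        out = {}
        for i, unit in enumerate(self.selected):
            variant = self._best_variant(unit.unit_id)
            fit = self.fits[unit.unit_id][variant]
            viz = visualize_axis(
                self.bases[variant], fit.beta, self.scores[variant],
                unit.mean_response, n_perm=cfg.n_perm, seed=seed + i,
                unit_id=unit.unit_id,
            )
            out[unit.unit_id] = {
                "variant": variant,
                "weights": viz.weights.tolist(),
                "weights_display": viz.weights_display.tolist(),
                "pvals": viz.pvals.tolist(),
                "significant": viz.significant.astype(bool).tolist(),
                "poses": {str(k): p.tolist() for k, p in viz.poses.items()},
            }
        path = self.out / "axis_inversion.json"
        path.write_text(json.dumps(out, indent=1, sort_keys=True))
        self._register("invert", [path], {"n_units": len(out)}, t0)

    def _stage_vii(self, t0):
        cfg = self.config
        seed = cfg.stage_seed("vii")
        rows = []
        for i, unit in enumerate(self.selected):
            variant = self._best_variant(unit.unit_id)
            fit = self.fits[unit.unit_id][variant]
            if fit.r2 <= cfg.r2_gate:
                continue
            from .view_invariance import compute_vii, predict_model_responses

            y_hat = predict_model_responses(
                self.matrices[variant], self.bases[variant], fit.beta
            )
            res = compute_vii(
                y_hat, self.matrices[variant].index,
                n_resamples=cfg.vii_resamples, seed=seed + i,
                unit_id=unit.unit_id,
            )
            rows.append(
                {"unit_id": unit.unit_id, "variant": variant, "r2": fit.r2,
                 "vii": res.vii, "observed_range": res.observed_range,
                 "best_pose": res.best_pose, "best_elevation": res.best_elevation}
            )
        path = self.out / "vii.csv"
        pd.DataFrame(rows, columns=["unit_id", "variant", "r2", "vii",
                                    "observed_range", "best_pose",
                                    "best_elevation"]).to_csv(path, index=False)
        self.vii_table = pd.DataFrame(rows) if rows else pd.DataFrame()
        self._register("vii", [path], {"n_units": len(rows)}, t0)

    def _stage_partition(self, t0):
        cfg = self.config
        seed = cfg.stage_seed("fit")  # identical folds as the component fits
        rows = []
        for i, unit in enumerate(self.selected):
            rel = self.selected_reliability[unit.unit_id]
            y = unit.mean_response
            kp_fit = self.fits[unit.unit_id][cfg.partition_variant]
            fb_fit = fit_pcr_cv(
                self.fb_scores, y, n_folds=cfg.n_folds, seed=seed + i,
                reliability=rel, unit_id=unit.unit_id, variant="feature_bank",
            )
            comb = fit_combined_model(
                self.scores[cfg.partition_variant], self.fb_scores, y,
                n_folds=cfg.n_folds, seed=seed + i, reliability=rel,
                unit_id=unit.unit_id,
            )
            part = variance_partition(kp_fit, fb_fit, comb)
            rows.append(
                {"unit_id": unit.unit_id, "r2_keypoint": part.r2_a,
                 "r2_feature_bank": part.r2_b, "r2_combined": part.r2_combined,
                 "unique_keypoint": part.unique_a,
                 "unique_feature_bank": part.unique_b, "shared": part.shared}
            )
        path = self.out / "variance_partition.csv"
        pd.DataFrame(rows, columns=["unit_id", "r2_keypoint", "r2_feature_bank",
                                    "r2_combined", "unique_keypoint",
                                    "unique_feature_bank", "shared"]
                     ).to_csv(path, index=False)
        self._register("partition", [path], {"n_units": len(rows)}, t0)

    def _stage_cluster(self, t0):
        cfg = self.config
        gated = [
            u.unit_id for u in self.selected
            if self.fits[u.unit_id][cfg.cluster_variant].r2 > cfg.r2_gate
        ]
        path = self.out / "clusters.json"
        if len(gated) < 2:
            path.write_text(json.dumps({"labels": {}, "summaries": {}}))
            self._register("cluster", [path], {"n_units": len(gated),
                                               "n_clusters": 0}, t0)
            return
        betas = np.stack(
            [self.fits[u][cfg.cluster_variant].beta for u in gated]
        )
        r2s = np.array([self.fits[u][cfg.cluster_variant].r2 for u in gated])
        res = cluster_axes(betas, metrics={"r2": r2s})
        out = {
            "variant": cfg.cluster_variant,
            "labels": dict(zip(gated, res.labels.astype(int).tolist())),
            "medoids": {str(k): gated[v] for k, v in res.medoids.items()},
            "summaries": {str(k): v for k, v in res.summaries.items()},
        }
        path.write_text(json.dumps(out, indent=1, sort_keys=True))
        self._register(
            "cluster", [path],
            {"n_units": len(gated), "n_clusters": res.n_clusters}, t0,
        )

    def _stage_decode(self, t0):
        cfg = self.config
        path = self.out / "decoding.json"
        conf_path = self.out / "confusion.csv"
        if not self.selected:
            path.write_text(json.dumps({"accuracy": None, "note": "no units"}))
            pd.DataFrame().to_csv(conf_path, index=False)
            self._register("decode", [path, conf_path], {"n_units": 0}, t0)
            return
        rates = np.stack([u.response_rates for u in self.selected])
        labels = self.pose_set.index["pose_id"].to_numpy()
        res = decode_poses(
            rates, labels, n_resamples=cfg.decode_resamples,
            n_label_perms=cfg.decode_label_perms,
            max_pseudotrials=cfg.decode_max_pseudotrials,
            seed=cfg.stage_seed("decode"),
        )
        path.write_text(json.dumps(
            {"accuracy_pct": res.accuracy, "accuracy_sd_pct": res.accuracy_sd,
             "chance_pct": res.chance_level, "perm_max_pct": res.perm_max,
             "classifier": res.classifier, "n_resamples": res.n_resamples},
            indent=1, sort_keys=True,
        ))
        pd.DataFrame(
            res.confusion, columns=[str(c) for c in res.classes]
        ).to_csv(conf_path, index=False)
        self._register(
            "decode", [path, conf_path],
            {"n_units": len(self.selected), "accuracy_pct": res.accuracy}, t0,
        )


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk)."""
    return Pipeline(config).run_all()
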