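"""Stimulus generator, silhouettes, and simulated-unit statistics."""

import numpy as np
import pytest

import posexis as px
from posexis import skeleton as sk
from posexis.synthetic_data import PoseSet, StimulusPose
from posexis.unit_selection import split_half_reliability_matrix


class TestPoseSet:
    def test_grid_structure(self, pose_set):
        assert pose_set.n_stimuli == 720
        assert pose_set.n_keypoints == 22
        idx = pose_set.index
        combos = set(zip(idx.pose_id, idx.azimuth_deg, idx.elevation_deg))
        assert len(combos) == 720
        assert set(idx.azimuth_deg) == {0.0, 45, 90, 135, 180, 225, 270, 315}
        assert set(idx.elevation_deg) == {0.0, 45.0}
        assert set(idx.pose_class) == set(range(1, 10))

    def test_coordinates_within_canvas(self, pose_set):
        xy = pose_set.coords[:, :, :2]
        assert np.all(np.isfinite(pose_set.coords))
        assert xy.min() >= 0.0 and xy.max() <= pose_set.image_size

    def test_determinism_and_seed_sensitivity(self):
        a = px.generate_pose_set(9, 4, seed=5)
        b = px.generate_pose_set(9, 4, seed=5)
        c = px.generate_pose_set(9, 4, seed=6)
        assert np.array_equal(a.coords, b.coords)
        assert not np.array_equal(a.coords, c.coords)

    @pytest.mark.parametrize("n_poses,n_views", [(0, 16), (45, 15), (45, 0)])
    def test_invalid_arguments(self, n_poses, n_views):
        with pytest.raises(ValueError):
            px.generate_pose_set(n_poses, n_views, seed=0)

    def test_azimuth_wraps_at_360(self):
        body = sk.build_skeleton(sk.class_parameters(5))
        np.testing.assert_allclose(
            sk.project_skeleton(body, 0, 45),
            sk.project_skeleton(body, 360, 45),
            atol=1e-12,
        )

    def test_mirror_views_of_symmetric_pose(self):
        """A bilaterally symmetric pose seen at 90 vs 270 degrees: x negates
        about the image center, y and depth match, up to L/R relabeling."""
        params = sk.class_parameters(5)
        for key in list(params):
            if key.startswith("l_"):
                params[key.replace("l_", "r_", 1)] = params[key]
        params["head_yaw"] = 0.0
        body = sk.build_skeleton(params)
        left = sk.project_skeleton(body, 90, 0)
        right = sk.project_skeleton(body, 270, 0)
        perm = np.arange(22)
        for l, r in sk.MIRROR_PAIRS.items():
            perm[sk.keypoint_index(l)] = sk.keypoint_index(r)
        relabeled = right[perm]
        np.testing.assert_allclose(left[:, 0], -relabeled[:, 0], atol=1e-12)
        np.testing.assert_allclose(left[:, 1:], relabeled[:, 1:], atol=1e-12)

    def test_csv_round_trip_is_exact(self, pose_set, tmp_path):
        path = tmp_path / "kp.csv"
        pose_set.to_csv(path)
        loaded = PoseSet.from_csv(path)
        assert np.array_equal(loaded.coords, pose_set.coords)
        assert loaded.keypoint_labels == pose_set.keypoint_labels


class TestSilhouettes:
    def test_stack_shape_and_binary(self, silhouettes):
        assert silhouettes.images.shape == (720, 25, 25)
        assert set(np.unique(silhouettes.images)) <= {0, 1}
        assert silhouettes.pixels.shape == (720, 625)

    def test_off_canvas_pose_renders_empty(self, pose_set):
        shifted = PoseSet(
            stimuli=[
                StimulusPose(
                    s.pose_id, s.pose_class, s.azimuth, s.elevation,
                    s.coords + np.array([2 * pose_set.image_size, 0.0, 0.0]),
                )
                for s in pose_set.stimuli[:3]
            ],
            image_size=pose_set.image_size,
        )
        stack = px.render_silhouettes(shifted, grid=25)
        assert stack.images.sum() == 0

    def test_invalid_grid(self, pose_set):
        with pytest.raises(ValueError):
            px.render_silhouettes(pose_set, grid=4)


class TestCategoryResponses:
    @pytest.mark.parametrize(
        "body,nonbody,expected",
        [(2.0, 1.0, 1 / 3), (3.0, 3.0, 0.0), (5.0, 0.0, 1.0)],
    )
    def test_noise_free_bsi(self, body, nonbody, expected):
        cat = px.simulate_category_responses(body, nonbody, noise="none", seed=0)
        assert px.compute_bsi(cat) == pytest.approx(expected, abs=1e-12)

    def test_partition_20_20_20(self):
        cat = px.simulate_category_responses(2.0, 1.0, seed=1)
        labels, counts = np.unique(cat["labels"], return_counts=True)
        assert sorted(labels) == ["body", "face", "object"]
        assert all(counts == 20)
        assert cat["response_rates"].shape == (5, 60)


class TestSimulatedUnits:
    def test_noise_free_units_are_deterministic_and_reliable(self, scores):
        units = px.simulate_encoding_units(
            scores["2D"], n_units=3, gain=20.0, target_reliability=None,
            noise="none", n_trials=4, seed=9, variant="2D",
        )
        u = units[0]
        beta = np.array(u.ground_truth["beta_true"])
        expected = np.maximum(10.0 + 20.0 * scores["2D"] @ beta, 0.0)
        np.testing.assert_allclose(u.mean_response, expected, atol=1e-12)
        assert np.all(u.response_rates == u.response_rates[0])

    def test_reliability_calibration_hits_target(self, scores):
        """Self-consistency: calibrating to 0.7 yields a realized median
        Spearman-Brown reliability within +/- 0.05."""
        units = px.simulate_encoding_units(
            scores["3D_VD"], n_units=50, target_reliability=0.7,
            n_trials=8, seed=42, variant="3D_VD",
        )
        rates = np.stack([u.response_rates for u in units])
        rel = split_half_reliability_matrix(
            rates, n_splits=100, rng=np.random.default_rng(0)
        )
        assert 0.65 <= np.median(rel) <= 0.75

    def test_untuned_units_reject_at_nominal_rate(self, scores):
        """gain = 0 leaves responses stimulus-independent; the selectivity
        test should reject at ~ the nominal 5% rate."""
        units = px.simulate_encoding_units(
            scores["2D"], n_units=200, gain=0.0, target_reliability=None,
            n_trials=6, seed=7,
        )
        pvals = [px.selectivity_test(u.response_rates) for u in units]
        rate = np.mean(np.array(pvals) < 0.05)
        assert 0.005 <= rate <= 0.10  # 3-sigma binomial band around 0.05

    def test_invalid_target_reliability(self, scores):
        with pytest.raises(ValueError):
            px.simulate_encoding_units(scores["2D"], 2, target_reliability=1.5)

    def test_determinism(self, scores):
        a = px.simulate_encoding_units(scores["2D"], 4, gain=15.0,
                                       target_reliability=None, seed=3)
        b = px.simulate_encoding_units(scores["2D"], 4, gain=15.0,
                                       target_reliability=None, seed=3)
        for ua, ub in zip(a, b):
            assert np.array_equal(ua.response_rates, ub.response_rates)
            assert np.array_equal(ua.baseline_rates, ub.baseline_rates)


class TestSurrogateFeatures:
    def test_identity_projection_reproduces_keypoints(self, matrices):
        feats = px.surrogate_feature_matrix(
            matrices["2D"], n_features=44, nonlinearity="identity",
            projection="identity",
        )
        np.testing.assert_array_equal(feats, matrices["2D"].X)

    def test_seed_determinism_and_rectification(self, silhouettes):
        a = px.surrogate_feature_matrix(silhouettes, 64, seed=5)
        b = px.surrogate_feature_matrix(silhouettes, 64, seed=5)
        assert np.array_equal(a, b)
        assert a.min() >= 0.0  # relu default
        assert a.shape == (720, 64)

    def test_features_retain_pose_information(self, silhouettes, pose_set):
        """Pose identity is decodable from 500 silhouette features far above
        the 2.22% chance level (the features keep shape information)."""
        feats = px.surrogate_feature_matrix(silhouettes, 500, seed=11)
        rates = np.stack([feats.T, feats.T])  # 2 identical "trials"
        rates = np.moveaxis(rates, 0, 1)  # (units, trials, stimuli)
        res = px.decode_poses(
            rates, pose_set.index["pose_id"].to_numpy(),
            n_resamples=1, max_pseudotrials=8, seed=0,
        )
        assert res.accuracy > 8 * res.chance_level


class TestRatesCsv:
    def test_round_trip(self, scores, tmp_path):
        units = px.simulate_encoding_units(scores["2D"][:40], 2, gain=12.0,
                                           target_reliability=None, seed=8)
        from posexis.synthetic_data import load_units_csv, save_units_csv

        save_units_csv(units, tmp_path / "r.csv", tmp_path / "gt.json")
        loaded = load_units_csv(tmp_path / "r.csv", tmp_path / "gt.json")
        assert [u.unit_id for u in loaded] == [u.unit_id for u in units]
        for ua, ub in zip(units, loaded):
            np.testing.assert_array_equal(ua.response_rates, ub.response_rates)
            assert ub.ground_truth["gain"] == ua.ground_truth["gain"]
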