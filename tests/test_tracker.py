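import numpy as np
import pytest

import ceustrack as ct
from ceustrack.io import BoundingBox
from ceustrack.synthetic import Distractor, SceneSpec, ShadowEvent, render_video
from ceustrack.tracker import Tracker


class TestInit:
    def test_frame_zero_returns_initial_box(self, static_scene_data):
        _, seq, gt = static_scene_data
        tracker = Tracker(seq[0], gt.boxes[0])
        assert tracker.result.boxes[0] == gt.boxes[0]

    def test_out_of_bounds_box_rejected(self, static_scene_data):
        _, seq, _ = static_scene_data
        with pytest.raises(ValueError):
            Tracker(seq[0], BoundingBox(2, 2, 24, 24))

    def test_degenerate_box_rejected(self, static_scene_data):
        _, seq, _ = static_scene_data
        with pytest.raises(ValueError):
            Tracker(seq[0], BoundingBox(50, 50, 1, 1))

    def test_initial_tic_sample_is_box_mean(self, static_scene_data):
        _, seq, gt = static_scene_data
        b = gt.boxes[0]
        tracker = Tracker(seq[0], b)
        x0, y0 = int(round(b.cx - (b.w - 1) / 2)), int(round(b.cy - (b.h - 1) / 2))
        expected = seq[0][y0 : y0 + int(b.h), x0 : x0 + int(b.w)].mean()
        assert tracker.tic.samples[0] == pytest.approx(expected)

    def test_bad_config_values_rejected(self):
        with pytest.raises(ValueError):
            ct.TrackerConfig(backend="resnet")
        with pytest.raises(ValueError):
            ct.TrackerConfig(fusion="additive")


class TestRun:
    def test_static_scene_tracked_within_one_pixel(self, static_scene_data):
        _, seq, gt = static_scene_data
        res = ct.run(seq, gt.boxes[0])
        errors = np.linalg.norm(
            res.centers() - np.array([[b.cx, b.cy] for b in gt.boxes]), axis=1
        )
        assert errors.max() <= 1.0

    def test_single_frame_sequence(self, static_scene_data):
        _, seq, gt = static_scene_data
        res = ct.run(seq.frames[:1], gt.boxes[0])
        assert len(res) == 1
        assert res.boxes[0] == gt.boxes[0]

    def test_empty_sequence_rejected(self, static_scene_data):
        _, _, gt = static_scene_data
        with pytest.raises(ValueError):
            ct.run(np.zeros((0, 64, 64)), gt.boxes[0])

    def test_ncc_backend_is_deterministic(self, static_scene_data):
        _, seq, gt = static_scene_data
        r1 = ct.run(seq, gt.boxes[0])
        r2 = ct.run(seq, gt.boxes[0])
        assert np.array_equal(r1.centers(), r2.centers())
        assert r1.abnormal == r2.abnormal

    def test_box_size_constant_translation_only(self, ablation_runs):
        res = ablation_runs["full"]
        assert all(b.w == res.boxes[0].w and b.h == res.boxes[0].h for b in res.boxes)

    def test_frame_shape_mismatch_names_frame(self, static_scene_data):
        _, seq, gt = static_scene_data
        tracker = Tracker(seq[0], gt.boxes[0])
        tracker.step(seq[1])
        with pytest.raises(ValueError, match="frame 2"):
            tracker.step(np.zeros((10, 10)))


@pytest.fixture(scope="module")
def shadow_run():
    spec = SceneSpec(
        frame_shape=(96, 128),
        n_frames=60,
        breathing_amplitude=(6.0, 2.0),
        breathing_period=30.0,
        shadow_events=(ShadowEvent(25, 8, 0.9),),
        seed=17,
    )
    seq, gt = render_video(spec)
    res = ct.run(seq, gt.boxes[0])
    return spec, seq, gt, res


class TestShadowHandling:
    def test_shadow_frames_flagged_abnormal(self, shadow_run):
        spec, _, _, res = shadow_run
        flagged = {i for i, a in enumerate(res.abnormal) if a}
        shadow = set(range(25, 33))
        # at least the bulk of the shadow is caught, nothing outside it
        assert flagged, "no abnormal frames detected"
        assert flagged <= shadow

    def test_no_matching_during_abnormal_frames(self, shadow_run):
        _, _, _, res = shadow_run
        for i, a in enumerate(res.abnormal):
            if a:
                assert np.isnan(res.scores[i])
                assert not res.measurement_used[i]

    def test_abnormal_box_is_kalman_prediction(self, shadow_run):
        _, _, _, res = shadow_run
        for i, a in enumerate(res.abnormal):
            if a:
                assert np.allclose(res.centers()[i], res.pred_centers[i])

    def test_tracker_recovers_after_shadow(self, shadow_run):
        _, _, gt, res = shadow_run
        errors = np.linalg.norm(
            res.centers() - np.array([[b.cx, b.cy] for b in gt.boxes]), axis=1
        )
        assert errors[-10:].max() < 4.0


class TestTemplateUpdateCadence:
    def test_updates_every_five_frames_without_abnormal(self, static_scene_data):
        _, seq, gt = static_scene_data
        tracker = Tracker(seq[0], gt.boxes[0])
        for i in range(1, len(seq)):
            tracker.step(seq[i])
        assert tracker.update_frames == list(range(0, len(seq), 5))

    def test_no_update_on_shadow_frames(self):
        spec = SceneSpec(
            frame_shape=(96, 128),
            n_frames=40,
            breathing_amplitude=(4.0, 2.0),
            shadow_events=(ShadowEvent(15, 6, 0.9),),
            seed=23,
        )
        seq, gt = render_video(spec)
        tracker = Tracker(seq[0], gt.boxes[0])
        for i in range(1, len(seq)):
            tracker.step(seq[i])
        abnormal = {i for i, a in enumerate(tracker.result.abnormal) if a}
        assert abnormal
        assert not (set(tracker.update_frames) & abnormal)


class TestAttentionGate:
    def test_identical_distractor_far_away_is_excluded(self):
        """A look-alike 40+ px away sits outside the attention mask
        (exp(-40^2/2*sigma^2) << 1e-4 for sigma <= 9), so the tracker never
        jumps to it."""
        lesion_curve = ct.PerfusionCurve(
            wash_in_rate=0.5, peak_time=4.0, wash_out_rate=0.15, baseline=0.1, peak=0.9
        )
        spec = SceneSpec(
            frame_shape=(160, 224),
            n_frames=60,
            lesion_center0=(80.0, 80.0),
            breathing_amplitude=(5.0, 2.0),
            distractors=(Distractor(offset=(64.0, 0.0), radius=12.0, curve=lesion_curve),),
            lesion_curve=lesion_curve,
            seed=31,
        )
        seq, gt = render_video(spec)
        res = ct.run(seq, gt.boxes[0])
        errors = np.linalg.norm(
            res.centers() - np.array([[b.cx, b.cy] for b in gt.boxes]), axis=1
        )
        assert errors.max() < 20.0  # never at the distractor (64 px away)

    def test_matched_center_stays_inside_valid_mask(self, ablation_runs):
        """On non-abnormal frames the output center is never in the region
        the attention map marks invalid (Att < 1e-4)."""
        res = ablation_runs["full"]
        mask_factor = np.sqrt(-2.0 * np.log(1e-4))
        for i in range(1, len(res)):
            if res.abnormal[i] or np.isnan(res.sigmas[i]):
                continue
            d = np.linalg.norm(res.centers()[i] - res.pred_centers[i])
            assert d <= res.sigmas[i] * mask_factor + 1e-9

    def test_lesion_near_border_does_not_crash(self):
        spec = SceneSpec(
            frame_shape=(96, 128),
            n_frames=30,
            lesion_center0=(18.0, 18.0),
            lesion_radius=10.0,
            breathing_amplitude=(4.0, 4.0),
            seed=37,
        )
        seq, gt = render_video(spec)
        res = ct.run(seq, gt.boxes[0])
        assert len(res) == 30
        H, W = spec.frame_shape
        for b in res.boxes:
            assert 0 <= b.cx < W and 0 <= b.cy < H
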