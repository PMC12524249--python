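"""Tag-loss rule, plane back-projection, cross-view mapping, matching
with rejection, and the mapping evaluation statistics."""

import math

import numpy as np
import pytest

from dualview import scene_sim
from dualview.camera_geometry import CameraModel, project
from dualview.crossview_mapping import (
    DetectionRecord,
    MatchOutcome,
    TagClass,
    apply_rigid_2d,
    backproject_to_plane,
    evaluate_mapping,
    fit_rigid_2d,
    is_tag_loss,
    map_topdown_to_panoramic,
    match_target,
)
from dualview.errors import (
    BehindCameraError,
    DegenerateRayError,
    InvalidArgumentError,
    UndefinedMetricError,
)
from dualview.scene_sim import MotionState, NoiseModel


def det(box, cls=TagClass.tag_not_visible, frame=0, ident=0):
    return DetectionRecord(frame=frame, id=ident, box=box, cls=cls)


def down_camera():
    """Physical camera at (0, 0, 3.4) looking straight down at the floor."""
    return CameraModel.from_intrinsics(
        fx=1000, fy=1000, cx=960, cy=540,
        R=np.diag([1.0, -1.0, -1.0]), T=(0.0, 0.0, 3.4),
        image_size=(1920, 1080))


class TestIsTagLoss:
    IMG = (1920, 1080)

    def test_interior_untagged_box(self):
        assert is_tag_loss(det((10, 10, 50, 50)), self.IMG)

    @pytest.mark.parametrize("box", [
        (0, 10, 50, 50),          # touches x=0
        (10, 0.5, 50, 50),        # < 1 px margin at the top
        (1900, 10, 50, 50),       # spills over the right edge
        (10, 1040, 50, 41),       # exactly touches the bottom margin limit
    ])
    def test_boundary_boxes_rejected(self, box):
        assert not is_tag_loss(det(box), self.IMG)

    def test_exactly_one_pixel_margin_accepted(self):
        assert is_tag_loss(det((1.0, 1.0, 1918.0 - 1.0, 1078.0 - 1.0)), self.IMG)

    def test_tag_visible_never_tag_loss(self):
        assert not is_tag_loss(det((10, 10, 50, 50), cls=TagClass.tag_visible),
                               self.IMG)


class TestBackprojectToPlane:
    def test_principal_point_on_axis(self):
        cam = down_camera()
        p = backproject_to_plane((960, 540), cam, plane_height=0.35)
        assert p == pytest.approx((0.0, 0.0, 0.35), abs=1e-12)

    def test_round_trip_random_floor_points(self, cameras):
        rng = np.random.default_rng(2)
        for cam in cameras:
            for _ in range(50):
                p = (rng.uniform(0.5, 4.5), rng.uniform(0.5, 5.0), 0.0)
                (u, v), _ = project(p, cam)
                q = backproject_to_plane((u, v), cam, 0.0)
                assert np.allclose(q, p, atol=1e-8)

    def test_horizontal_ray_degenerate(self):
        cam = CameraModel.from_intrinsics(
            1000, 1000, 960, 540,
            R=np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [1.0, 0.0, 0.0]]),
            T=(0.0, 0.0, 0.0), image_size=(1920, 1080))
        # optical axis along world +X: the principal ray never meets Z=const
        with pytest.raises(DegenerateRayError):
            backproject_to_plane((960, 540), cam, plane_height=1.0)

    def test_intersection_behind_camera(self):
        cam = down_camera()
        with pytest.raises(BehindCameraError):
            backproject_to_plane((960, 540), cam, plane_height=5.0)


class TestMapTopdownToPanoramic:
    def test_identical_cameras_identity(self):
        cam = down_camera()
        d = det((950, 530, 20, 20))
        mapped = map_topdown_to_panoramic(d, cam, cam, plane_height=0.35)
        assert mapped == pytest.approx(d.center, abs=1e-9)

    def test_matches_direct_projection_on_simulated_scene(self, pen, cameras):
        cam_top, cam_pan = cameras
        trs = scene_sim.simulate_trajectories(pen, 10, 1.0, seed=3)
        res = scene_sim.render_views(trs, cam_top, cam_pan, NoiseModel.none(),
                                     seed=4)
        by_agent = {t.agent_id: t for t in trs}
        checked = 0
        for r in res.top:
            x, y = by_agent[r.id].positions[r.frame, 1:3]
            (u, v), _ = project((x, y, 0.35), cam_pan)
            mapped = map_topdown_to_panoramic(r, cam_top, cam_pan,
                                              plane_height=0.35)
            assert math.hypot(mapped[0] - u, mapped[1] - v) < 1e-6
            checked += 1
        assert checked > 100

    def test_point_outside_panoramic_frustum(self):
        cam_top = down_camera()
        # panoramic camera at the origin looking up: floor points behind it
        cam_pan = CameraModel.from_intrinsics(
            1000, 1000, 960, 540, R=np.eye(3), T=(0.0, 0.0, -1.0),
            image_size=(1920, 1080))
        with pytest.raises(BehindCameraError):
            map_topdown_to_panoramic(det((950, 530, 20, 20)), cam_top,
                                     cam_pan, plane_height=0.35)


class TestMatchTarget:
    IMG = (1920, 1080)
    DIAG = math.hypot(1920, 1080)

    def candidates_at(self, norm_dists, P2=(500.0, 500.0)):
        return [det((P2[0] + d * self.DIAG - 5.0, P2[1] - 5.0, 10, 10),
                    ident=i) for i, d in enumerate(norm_dists)]

    def test_nearest_below_threshold_matches(self):
        cands = self.candidates_at([0.010, 0.050])
        out = match_target((500.0, 500.0), cands, 0.025, self.IMG)
        assert not out.rejected
        assert out.matched.id == 0
        assert out.norm_distance == pytest.approx(0.010, abs=1e-12)

    def test_nearest_above_threshold_rejected(self):
        out = match_target((500.0, 500.0), self.candidates_at([0.030]),
                           0.025, self.IMG)
        assert out.rejected and out.matched is None
        assert out.norm_distance == pytest.approx(0.030, abs=1e-12)

    def test_no_candidates_rejected_inf(self):
        out = match_target((10.0, 10.0), [], 0.025, self.IMG)
        assert out.rejected and out.norm_distance == math.inf

    def test_tie_breaks_to_lowest_index(self):
        a = det((90.0, 100.0, 20, 20), ident=4)
        b = det((110.0, 100.0, 20, 20), ident=9)  # same distance, higher index
        out = match_target((105.0, 110.0), [a, b], 0.5, self.IMG)
        assert out.matched.id == 4

    def test_threshold_must_be_positive(self):
        with pytest.raises(InvalidArgumentError):
            match_target((0, 0), [], 0.0, self.IMG)

    def test_outcome_consistency_enforced(self):
        with pytest.raises(InvalidArgumentError):
            MatchOutcome(query=det((0, 0, 1, 1)), mapped_pixel=(0, 0),
                         matched=None, norm_distance=0.1, rejected=False)


class TestEvaluateMapping:
    def build(self, n_correct, n_wrong, n_rejected):
        outcomes, truth = [], {}
        i = 0
        for kind in (["c"] * n_correct + ["w"] * n_wrong + ["r"] * n_rejected):
            q = det((0, 0, 5, 5), frame=0, ident=i)
            truth[(0, i)] = (100.0 * i, 100.0, 20.0, 20.0)
            if kind == "r":
                outcomes.append(MatchOutcome(q, (0, 0), None, 1.0, True))
            else:
                box = truth[(0, i)] if kind == "c" else (5000.0, 5000.0, 20.0, 20.0)
                outcomes.append(MatchOutcome(
                    q, (0, 0), det(box, ident=i), 0.01, False))
            i += 1
        return outcomes, truth

    def test_worked_example(self):
        # 10 queries: 1 rejected, 8 of 9 matches correct
        outcomes, truth = self.build(8, 1, 1)
        ev = evaluate_mapping(outcomes, truth)
        assert ev.coverage == pytest.approx(0.9)
        assert ev.matching_accuracy == pytest.approx(8 / 9)
        assert ev.mapping_accuracy == pytest.approx(0.8)
        assert ev.rejection_rate == pytest.approx(0.1)

    def test_all_correct(self):
        ev = evaluate_mapping(*self.build(5, 0, 0))
        assert (ev.matching_accuracy, ev.coverage, ev.mapping_accuracy,
                ev.rejection_rate) == (1.0, 1.0, 1.0, 0.0)

    def test_all_rejected_matching_accuracy_undefined(self):
        ev = evaluate_mapping(*self.build(0, 0, 4))
        assert ev.coverage == 0.0 and ev.mapping_accuracy == 0.0
        assert ev.rejection_rate == 1.0
        assert math.isnan(ev.matching_accuracy)
        assert not ev.matching_accuracy_defined

    def test_accuracy_bounds(self):
        ev = evaluate_mapping(*self.build(3, 2, 2))
        assert ev.mapping_accuracy <= ev.coverage
        assert ev.mapping_accuracy <= ev.matching_accuracy

    def test_empty_outcomes_error(self):
        with pytest.raises(UndefinedMetricError):
            evaluate_mapping([], {})


class TestThresholdMonotonicity:
    def test_coverage_monotone_accuracy_bounded(self, pen, cameras):
        cam_top, cam_pan = cameras
        trs = scene_sim.simulate_trajectories(pen, 60, 1.0, seed=21,
                                              motion_state=MotionState.stationary)
        noisy = scene_sim.render_views(trs, cam_top, cam_pan,
                                       NoiseModel.day(), seed=22)
        clean = scene_sim.render_views(trs, cam_top, cam_pan,
                                       NoiseModel.none(), seed=22)
        truth = {(r.frame, r.id): r.box for r in clean.pan}
        pan_by_frame = {}
        for r in noisy.pan:
            pan_by_frame.setdefault(r.frame, []).append(r)
        queries = [(r, map_topdown_to_panoramic(r, cam_top, cam_pan, 0.35))
                   for r in noisy.top
                   if is_tag_loss(r, cam_top.image_size)
                   and (r.frame, r.id) in truth]
        assert len(queries) > 50
        coverages = []
        for th in [0.005, 0.01, 0.02, 0.025, 0.03, 0.05]:
            outs = [match_target(p2, pan_by_frame.get(q.frame, []), th,
                                 cam_pan.image_size, query=q)
                    for q, p2 in queries]
            ev = evaluate_mapping(outs, truth)
            coverages.append(ev.coverage)
            assert ev.mapping_accuracy <= ev.coverage + 1e-12
        assert all(b >= a - 1e-12 for a, b in zip(coverages, coverages[1:]))


class TestRigid2D:
    def test_fit_recovers_similarity(self):
        rng = np.random.default_rng(30)
        theta, scale = 0.4, 1.7
        A_true = scale * np.array([[np.cos(theta), -np.sin(theta)],
                                   [np.sin(theta), np.cos(theta)]])
        t_true = np.array([12.0, -3.0])
        src = rng.uniform(0, 100, size=(20, 2))
        dst = src @ A_true.T + t_true
        A, t = fit_rigid_2d(src, dst)
        assert np.allclose(A, A_true, atol=1e-9)
        assert np.allclose(t, t_true, atol=1e-7)
        assert apply_rigid_2d(src[0], A, t) == pytest.approx(tuple(dst[0]))

    def test_too_few_pairs(self):
        with pytest.raises(InvalidArgumentError):
            fit_rigid_2d(np.zeros((1, 2)), np.zeros((1, 2)))
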