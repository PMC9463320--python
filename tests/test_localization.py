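import numpy as np
import pytest

from monoloc import (
    CenterlineBranch,
    CenterlineTree,
    branch_accuracy,
    localize,
    localize_sequence,
    pose_to_geometry,
    project_point,
    resample,
)
from monoloc.localization import LocalizationError, brute_force_nearest
from monoloc.phantom import (
    PhantomSpec,
    default_pose,
    make_phantom,
    make_superimposed_scene,
    project_markers,
)

from conftest import random_pose


def random_scene(rng):
    """A random pose plus a random two-branch centerline near the iso-center."""
    geom = pose_to_geometry(random_pose(rng))
    branches = []
    for k in range(2):
        start = rng.uniform(-40, 40, 3)
        direction = rng.normal(0, 1, 3)
        direction /= np.linalg.norm(direction)
        t = np.linspace(0, rng.uniform(30, 70), rng.integers(40, 120))
        curve = start + np.outer(t, direction) + 5 * np.column_stack([
            np.sin(t / 17), np.cos(t / 23), np.sin(t / 31)
        ])
        branches.append(CenterlineBranch(f"b{k}", curve))
    return geom, CenterlineTree(branches)


class TestLocalize:
    def test_self_consistency_on_centerline_point(self, identity_geom, phantom_scene):
        _, tree, _, _ = phantom_scene
        work = resample(tree, 0.5)
        b = work["carotid"]
        k = 40
        p2d = project_point(identity_geom, b.points_mm[k])
        res = localize(identity_geom, p2d, work)
        assert (res.branch_id, res.index) == ("carotid", k)
        assert res.objective == pytest.approx(0.0, abs=1e-12)
        assert res.perp_dist_mm == pytest.approx(0.0, abs=1e-9)

    def test_cross_product_objective_equals_scaled_ray_distance(self, rng):
        """|| (c-s) x (p'-s) || = ||p'-s|| * dist(c, ray): the argmin of the
        printed objective coincides with the nearest point-to-ray search."""
        from monoloc.geometry import WorkingPoint2D, pixel_to_detector_point, pixel_to_ray

        geom, tree = random_scene(rng)
        p2d = WorkingPoint2D(rng.uniform(100, 400), rng.uniform(100, 400))
        ray_len = np.linalg.norm(
            pixel_to_detector_point(geom, p2d).point_mm - geom.source_mm
        )
        ray = pixel_to_ray(geom, p2d)
        res = localize(geom, p2d, tree)
        assert np.sqrt(res.objective) / ray_len == pytest.approx(
            ray.distance_to(res.point_mm), rel=1e-9
        )

    @pytest.mark.parametrize("n_scenes", [300])
    def test_oracle_equivalence_random_scenes(self, rng, n_scenes):
        """The cross-product argmin picks exactly the index found by the
        independent perpendicular-distance minimizer."""
        from monoloc.geometry import WorkingPoint2D

        for _ in range(n_scenes):
            geom, tree = random_scene(rng)
            p2d = WorkingPoint2D(rng.uniform(50, 460), rng.uniform(50, 460))
            res = localize(geom, p2d, tree)
            bid, idx, dist = brute_force_nearest(geom, p2d, tree)
            assert (res.branch_id, res.index) == (bid, idx)
            assert res.perp_dist_mm == pytest.approx(dist, rel=1e-9, abs=1e-12)

    def test_superimposed_branches_flagged_ambiguous(self, identity_geom):
        """A second branch lying on the same projection rays with aligned
        sampling produces a near-tie on the objective, which is flagged."""
        sod = identity_geom.pose.sod_mm
        depth = 3.0
        k = (sod + depth) / sod
        t = np.arange(0.0, 30.0 + 1e-9, 1.0)
        near = CenterlineBranch(
            "near", np.column_stack([np.zeros_like(t), np.zeros_like(t), t])
        )
        far = CenterlineBranch(
            "far",
            np.column_stack([np.zeros_like(t), np.full_like(t, depth), k * t]),
        )
        tree = CenterlineTree([near, far])
        # a device point between two samples: both branches miss it by the
        # same half-sample margin (up to the depth scale factor)
        p2d = project_point(identity_geom, np.array([0.0, 0.0, 8.5]))
        res = localize(identity_geom, p2d, tree)
        assert res.ambiguous

    def test_empty_candidates_rejected(self, identity_geom, phantom_scene):
        from monoloc.geometry import WorkingPoint2D

        _, tree, _, _ = phantom_scene
        with pytest.raises(LocalizationError, match="empty"):
            localize(identity_geom, WorkingPoint2D(100, 100), tree, candidates=[])

    def test_candidate_restriction_respected(self, identity_geom, phantom_scene):
        _, tree, _, _ = phantom_scene
        work = resample(tree, 0.5)
        p2d = project_point(identity_geom, work["carotid"].points_mm[60])
        cand = {("arch", i) for i in range(work["arch"].n_points)}
        res = localize(identity_geom, p2d, work, candidates=cand)
        assert res.branch_id == "arch"
        assert res.n_candidates == len(cand)


class TestErrorBounds:
    def test_on_centerline_markers_within_half_spacing(self, identity_geom):
        """Markers on the resampled centerline, real-valued pixels: the 3D
        error cannot exceed half the resampling distance."""
        spec = PhantomSpec(marker_arc_positions_mm=(9.1, 17.3, 24.9, 33.7, 41.2),
                           seed=11)
        tree, markers, _ = make_phantom(spec)
        work = resample(tree, 0.5)
        pts = project_markers(identity_geom, markers)
        for p2d, m in zip(pts, markers):
            res = localize(identity_geom, p2d, work)
            assert np.linalg.norm(res.point_mm - m) <= 0.25 + 1e-9

    def test_quantized_pixels_add_footprint_bound(self, identity_geom):
        spec = PhantomSpec(marker_arc_positions_mm=(9.1, 17.3, 24.9, 33.7, 41.2),
                           seed=11)
        tree, markers, _ = make_phantom(spec)
        work = resample(tree, 0.5)
        pose = identity_geom.pose
        qbound = pose.pixel_spacing_mm[0] * pose.sid_mm / pose.sod_mm * np.sqrt(2) / 2
        pts = project_markers(identity_geom, markers, quantize=True)
        for p2d, m in zip(pts, markers):
            res = localize(identity_geom, p2d, work)
            assert np.linalg.norm(res.point_mm - m) <= 0.25 + qbound + 1e-9

    def test_radial_offset_bounded_by_vessel_radius_margin(self, identity_geom):
        """Markers off the centerline by the carotid radius localize within
        radius + half-spacing (+ quantization footprint when quantized)."""
        r = 3.2
        pose = identity_geom.pose
        qbound = pose.pixel_spacing_mm[0] * pose.sid_mm / pose.sod_mm * np.sqrt(2) / 2
        for seed in range(10):
            spec = PhantomSpec(marker_radial_offset_mm=(r,) * 5, seed=seed)
            tree, markers, _ = make_phantom(spec)
            work = resample(tree, 0.5)
            for quantize, bound in ((False, r + 0.25), (True, r + 0.25 + qbound)):
                pts = project_markers(identity_geom, markers, quantize=quantize)
                for p2d, m in zip(pts, markers):
                    res = localize(identity_geom, p2d, work)
                    assert np.linalg.norm(res.point_mm - m) <= bound + 1e-9

    def test_refining_spacing_never_hurts(self, identity_geom):
        """Halving the resampling spacing never increases the achievable
        point-to-ray distance minimum."""
        spec = PhantomSpec(marker_arc_positions_mm=(13.7,), seed=2,
                           marker_radial_offset_mm=(1.5,))
        tree, markers, _ = make_phantom(spec)
        p2d = project_markers(identity_geom, markers)[0]
        prev = np.inf
        for spacing in (4.0, 2.0, 1.0, 0.5):
            work = resample(tree, spacing)
            _, _, dist = brute_force_nearest(identity_geom, p2d, work)
            assert dist <= prev + 1e-9
            prev = dist


class TestSequence:
    def test_single_point_no_init_equals_full_search(self, identity_geom, phantom_scene):
        _, tree, markers, _ = phantom_scene
        work = resample(tree, 0.5)
        p2d = project_markers(identity_geom, markers[:1])[0]
        seq = localize_sequence(identity_geom, [p2d], work, window_mm=10)
        single = localize(identity_geom, p2d, work)
        assert (seq[0].branch_id, seq[0].index) == (single.branch_id, single.index)

    def test_continuity_fixes_superimposed_branches(self):
        """Unconstrained search jumps to the superimposed decoy branch for
        some of the 20 points; the geodesic window keeps all 20 on the true
        branch."""
        tree, geom, pixels, _, truth_branch = make_superimposed_scene()
        unconstrained = [localize(geom, p, tree) for p in pixels]
        acc_free = branch_accuracy(unconstrained, [truth_branch] * len(pixels))
        assert acc_free < 1.0

        init = localize(geom, pixels[0], tree,
                        candidates={(truth_branch, i)
                                    for i in range(tree[truth_branch].n_points)})
        constrained = localize_sequence(geom, pixels, tree, window_mm=10, init=init)
        assert branch_accuracy(constrained, [truth_branch] * len(pixels)) == 1.0

    def test_pull_through_is_monotone(self, identity_geom):
        """Markers advancing along the carotid produce non-decreasing
        arc-length positions."""
        arcs = tuple(np.linspace(5, 55, 26))
        spec = PhantomSpec(marker_arc_positions_mm=arcs,
                           marker_radial_offset_mm=(0.0,) * len(arcs), seed=3)
        tree, markers, _ = make_phantom(spec)
        work = resample(tree, 0.5)
        pts = project_markers(identity_geom, markers, quantize=True)
        results = localize_sequence(identity_geom, pts, work, window_mm=10)
        assert all(r.branch_id == "carotid" for r in results)
        pos = [work["carotid"].cum_arclen_mm[r.index] for r in results]
        assert all(b >= a - 1e-9 for a, b in zip(pos, pos[1:]))

    def test_sequence_validation(self, identity_geom, phantom_scene):
        _, tree, _, _ = phantom_scene
        with pytest.raises(LocalizationError, match="empty"):
            localize_sequence(identity_geom, [], tree)


class TestBranchAccuracy:
    def test_all_correct(self):
        tree, geom, pixels, _, truth = make_superimposed_scene()
        res = [localize(geom, p, tree,
                        candidates={(truth, i) for i in range(tree[truth].n_points)})
               for p in pixels[:4]]
        assert branch_accuracy(res, [truth] * 4) == 1.0

    def test_fraction_matches_count(self):
        tree, geom, pixels, _, truth = make_superimposed_scene()
        res = [localize(geom, p, tree) for p in pixels]
        truths = [truth] * len(res)
        expected = sum(r.branch_id == truth for r in res) / len(res)
        assert branch_accuracy(res, truths) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(LocalizationError):
            branch_accuracy([], [])
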