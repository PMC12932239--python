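import numpy as np
import pytest

from needleplan.geometry import NeedleTrajectory, points_line_distance
from needleplan.refine import (
    ObstacleSphere,
    RefineConfig,
    constraint_residuals,
    envelope_obstacle,
    feasibility_report,
    objective,
    refine_needles,
)


def make_needle(p_s, p_t, seed_ids):
    p_s, p_t = np.asarray(p_s, float), np.asarray(p_t, float)
    return NeedleTrajectory(p_s=p_s, p_t=p_t,
                            length=float(np.linalg.norm(p_s - p_t)),
                            assigned_seed_ids=list(seed_ids))


BOX = np.array([[-300.0, -300.0, -300.0], [300.0, 300.0, 300.0]])


def base_config(**kw):
    kw.setdefault("workspace_box", BOX)
    kw.setdefault("depth_mode", "literal")
    kw.setdefault("l_max", 250.0)
    kw.setdefault("needle_length", 200.0)
    return RefineConfig(**kw)


class TestEnvelope:
    def test_single_point(self):
        spheres = envelope_obstacle(np.array([[1.0, 2.0, 3.0]]), 1, margin=2.0)
        assert len(spheres) == 1
        assert spheres[0].center == pytest.approx([1, 2, 3])
        assert spheres[0].radius == pytest.approx(2.0)

    def test_segment_coverage_two_spheres(self):
        pts = np.stack([np.linspace(0, 40, 41), np.zeros(41), np.zeros(41)], axis=1)
        spheres = envelope_obstacle(pts, 2, margin=0.5)
        assert len(spheres) == 2
        for p in pts:  # every obstacle point covered by at least one sphere
            assert min(np.linalg.norm(p - s.center) for s in spheres) <= spheres[0].radius

    def test_ball_mask_recovers_center_and_radius(self):
        spacing = np.array([1.0, 1.0, 1.0])
        origin = np.array([-12.0, -12.0, -12.0])
        idx = np.indices((25, 25, 25)).reshape(3, -1).T
        world = origin + idx * spacing
        mask = (np.linalg.norm(world - [0, 0, 0], axis=1) <= 5.0).reshape(25, 25, 25)
        spheres = envelope_obstacle(mask.astype(np.uint8), 1, margin=0.0,
                                    origin=origin, spacing=spacing)
        assert np.linalg.norm(spheres[0].center) <= 1.0  # within one voxel of center
        assert spheres[0].radius >= 5.0 - 1.0

    def test_empty_obstacle(self):
        with pytest.raises(ValueError):
            envelope_obstacle(np.empty((0, 3)), 1)


class TestObjective:
    def test_zero_when_collinear(self):
        nd = make_needle((0, 0, -100), (0, 0, 100), [0, 1])
        seeds = np.array([[0, 0, 10], [0, 0, -30]], float)
        assert objective([nd], seeds, [0, 1]) == 0.0

    def test_sum_of_perpendicular_offsets(self):
        nd = make_needle((0, 0, -100), (0, 0, 100), [0, 1])
        seeds = np.array([[1, 0, 10], [0, 2, -30]], float)
        assert objective([nd], seeds, [0, 1]) == pytest.approx(3.0)

    def test_matches_double_loop_oracle(self, rng):
        needles, seeds, ids = [], [], []
        k = 0
        for _ in range(4):
            nd = make_needle(rng.uniform(-50, 50, 3), rng.uniform(-50, 50, 3), [])
            grp = []
            for _ in range(3):
                seeds.append(rng.uniform(-50, 50, 3))
                grp.append(k)
                ids.append(k)
                k += 1
            nd.assigned_seed_ids = grp
            needles.append(nd)
        seeds = np.array(seeds)
        expected = 0.0
        for nd in needles:
            for s in nd.assigned_seed_ids:
                expected += points_line_distance(seeds[[s]], nd.p_s, nd.p_t)[0]
        assert objective(needles, seeds, ids) == pytest.approx(expected, abs=1e-9)

    def test_unassigned_seed_rejected(self):
        nd = make_needle((0, 0, 0), (0, 0, 10), [0])
        with pytest.raises(ValueError):
            objective([nd], np.zeros((2, 3)), [0, 1])


class TestResiduals:
    def test_boundary_hub_separation(self):
        n1 = make_needle((0, 0, 200), (0, 0, 0), [0])
        n2 = make_needle((20, 0, 200), (20, 0, 0), [1])
        rt = constraint_residuals([n1, n2], [], base_config(d_g=20.0))
        assert rt.separation[0] == pytest.approx(0.0, abs=1e-12)

    def test_obstacle_clearance_value(self):
        nd = make_needle((0, 0, 200), (0, 0, 0), [0])
        obs = [ObstacleSphere(center=(5, 0, 50), radius=4.0)]
        rt = constraint_residuals([nd], obs, base_config())
        assert rt.obstacle[0, 0] == pytest.approx(1.0)

    def test_random_configuration_matches_direct_formulas(self, rng):
        cfg = base_config(d_g=15.0, l_min=10.0)
        needles = [make_needle(rng.uniform(50, 250, 3), rng.uniform(-30, 30, 3), [i])
                   for i in range(3)]
        obs = [ObstacleSphere(center=rng.uniform(-40, 40, 3), radius=3.0)]
        rt = constraint_residuals(needles, obs, cfg)
        for i, nd in enumerate(needles):
            depth = np.linalg.norm(nd.p_t - nd.p_s)
            assert rt.accessibility[i] == pytest.approx(cfg.l_max - depth)
            assert rt.stability[i] == pytest.approx(depth - cfg.l_min)
            d = points_line_distance(np.array([obs[0].center]), nd.p_s, nd.p_t)[0]
            assert rt.obstacle[i, 0] == pytest.approx(d - 3.0)
            assert rt.length[i] == pytest.approx(abs(depth - cfg.needle_length))
        assert rt.separation[0] == pytest.approx(
            np.linalg.norm(needles[0].p_s - needles[1].p_s) - 15.0)

    def test_entry_depth_through_spherical_body(self):
        cfg = RefineConfig(workspace_box=BOX,
                           body_surface={"type": "sphere", "center": [0, 0, 0],
                                         "radius": 80.0})
        nd = make_needle((0, 0, 200), (0, 0, 0), [0])
        rt = constraint_residuals([nd], [], cfg)
        # entry at z = 80 on the way down to the tip at the center
        assert rt.accessibility[0] == pytest.approx(cfg.l_max - 80.0)


class TestRefine:
    def test_feasible_start_is_left_alone(self):
        seeds = np.array([[0, 0, 0], [0, 0, 6], [30, 0, 0], [30, 0, 6]], float)
        n1 = make_needle((0, 0, 200), (0, 0, 0), [0, 1])
        n2 = make_needle((30, 0, 200), (30, 0, 0), [2, 3])
        cfg = base_config()
        plan = refine_needles([n1, n2], seeds, [0, 1, 2, 3], [], cfg)
        assert plan.err == pytest.approx(0.0, abs=1e-6)
        assert plan.modified_count == 0
        assert all(nd.feasible for nd in plan.needles)
        assert plan.seed_plan["displacement_mm"].max() == pytest.approx(0.0, abs=1e-6)

    def test_obstacle_forces_only_that_needle_to_move(self):
        seeds = np.array([[0, 0, 0], [0, 0, 6], [40, 0, 0], [40, 0, 6]], float)
        n1 = make_needle((0, 0, 200), (0, 0, 0), [0, 1])
        n2 = make_needle((40, 0, 200), (40, 0, 0), [2, 3])
        obs = [ObstacleSphere(center=(0.5, 0, 100), radius=3.0)]
        cfg = base_config()
        plan = refine_needles([n1, n2], seeds, [0, 1, 2, 3], obs, cfg)
        assert plan.residuals.obstacle.min() >= -1e-5
        assert plan.needles[0].modified
        assert not plan.needles[1].modified

    def test_close_hubs_are_separated(self):
        seeds = np.array([[0, 0, 0], [0, 0, 6], [10, 0, 0], [10, 0, 6]], float)
        n1 = make_needle((0, 0, 200), (0, 0, 0), [0, 1])
        n2 = make_needle((10, 0, 200), (10, 0, 0), [2, 3])
        cfg = base_config(d_g=20.0)
        plan = refine_needles([n1, n2], seeds, [0, 1, 2, 3], [], cfg)
        hubs = [nd.p_s for nd in plan.needles]
        assert np.linalg.norm(hubs[0] - hubs[1]) >= 20.0 - 1e-5

    def test_refined_length_equals_needle_length(self):
        seeds = np.array([[0, 0, 0], [0, 0, 6], [10, 0, 0], [10, 0, 6]], float)
        n1 = make_needle((0, 0, 200), (0, 0, 0), [0, 1])
        n2 = make_needle((10, 0, 200), (10, 0, 0), [2, 3])
        plan = refine_needles([n1, n2], seeds, [0, 1, 2, 3], [],
                              base_config(d_g=20.0))
        for nd in plan.needles:
            if nd.feasible:
                assert abs(np.linalg.norm(nd.p_s - nd.p_t) - 200.0) <= 1e-6

    def test_displacement_equals_distance_to_final_axis(self):
        seeds = np.array([[0.4, 0, 0], [0, 0.3, 6], [10, 0, 0], [10, 0, 6]], float)
        n1 = make_needle((0, 0, 200), (0, 0, 0), [0, 1])
        n2 = make_needle((10, 0, 200), (10, 0, 0), [2, 3])
        plan = refine_needles([n1, n2], seeds, [0, 1, 2, 3], [], base_config())
        for _, row in plan.seed_plan.iterrows():
            if row["missed"]:
                continue
            nd = plan.needles[int(row["needle_index"])]
            d = points_line_distance(
                np.array([[row["x_mm"], row["y_mm"], row["z_mm"]]]), nd.p_s, nd.p_t)[0]
            assert row["displacement_mm"] == pytest.approx(d, abs=1e-9)

    def test_deterministic(self):
        seeds = np.array([[0, 0, 0], [0, 0, 6], [10, 0, 0], [10, 0, 6]], float)
        def build():
            return [make_needle((0, 0, 200), (0, 0, 0), [0, 1]),
                    make_needle((10, 0, 200), (10, 0, 0), [2, 3])]
        p1 = refine_needles(build(), seeds, [0, 1, 2, 3], [], base_config(d_g=20.0))
        p2 = refine_needles(build(), seeds, [0, 1, 2, 3], [], base_config(d_g=20.0))
        assert np.array_equal(np.array([nd.p_s for nd in p1.needles]),
                              np.array([nd.p_s for nd in p2.needles]))

    def test_workspace_violation_marks_seeds_missed(self):
        seeds = np.array([[0, 0, 0], [0, 0, 6]], float)
        nd = make_needle((0, 0, 200), (0, 0, 0), [0, 1])
        tight_box = np.array([[-500.0, -500.0, -500.0], [500.0, 500.0, 100.0]])
        cfg = base_config(workspace_box=tight_box, r_search=2.0,
                          enlargement_factor=1.5, max_enlargements=1)
        plan = refine_needles([nd], seeds, [0, 1], [], cfg)
        assert not plan.needles[0].feasible
        rep = feasibility_report(plan, cfg)
        assert rep["missed_seeds"] == 2

    def test_inconsistent_config_rejected(self):
        with pytest.raises(ValueError):
            RefineConfig(l_max=10.0, l_min=20.0)


class TestFeasibilityReport:
    def test_all_positive_residuals_all_feasible(self):
        seeds = np.array([[0, 0, 0], [0, 0, 6], [40, 0, 0], [40, 0, 6]], float)
        n1 = make_needle((0, 0, 200), (0, 0, 0), [0, 1])
        n2 = make_needle((40, 0, 200), (40, 0, 0), [2, 3])
        plan = refine_needles([n1, n2], seeds, [0, 1, 2, 3], [], base_config())
        rep = feasibility_report(plan, base_config())
        assert rep["feasible_needles"] == 2
        assert rep["missed_seeds"] == 0
        assert rep["max_displacement_mm"] == pytest.approx(0.0, abs=1e-6)
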