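import itertools
import math

import numpy as np
import pytest

from vasctree.dcco_growth import (
    CostFunctional,
    GrowthError,
    StageConfig,
    candidate_bifurcation_points,
    grow,
    is_valid_connection,
    neighbourhood,
    neighbourhood_size,
    run_stages,
    tree_cost,
    try_insert,
    vessel_cost,
    _seg_seg_distance,
)
from vasctree.domain_geometry import BoxDomain
from vasctree.morphometry import intravascular_volume
from vasctree.vessel_tree import (
    VascularTree,
    add_terminal,
    assign_terminal_flows,
    rescale_radii,
)

from conftest import build_random_tree

UNIT_BOX = BoxDomain([0, 0, 0], [1, 1, 1], seed=0)


def _seed_tree(r0=0.05, Q_in=1.0):
    return VascularTree.from_root([0, 0.5, 0.5], [0.2, 0.5, 0.5],
                                  r0=r0, Q_in=Q_in)


class TestCostFunctional:
    def test_volumetric_reduction(self):
        # sprouting with gamma=3, c_v=1, unit references equals pi*l*r^2
        F = CostFunctional.sprouting(1.0, 0.0, 0.0, V_ref=1.0, l_ref=1.0,
                                     r_ref=1.0, gamma=3.0)
        v = _seed_tree().root
        v.x_d = np.array([1.0, 0.5, 0.5])
        v.x_p = np.array([0.0, 0.5, 0.5])
        v.r = 1.0
        assert vessel_cost(v, F) == pytest.approx(math.pi, rel=1e-14)
        assert vessel_cost(v, CostFunctional.volumetric()) == pytest.approx(
            math.pi, rel=1e-14)

    def test_staged_coefficients_hand_evaluation(self):
        F = CostFunctional.sprouting(0.999, 0.0, 0.001, V_ref=100.0,
                                     l_ref=1.0, r_ref=1.0, gamma=3.0)
        v = _seed_tree().root
        v.x_p = np.array([0.0, 0.0, 0.0])
        v.x_d = np.array([1.0, 0.0, 0.0])
        v.r = 0.1
        expected = 0.999 * math.pi * 1.0 * 0.01 / 100.0 + 0.001 * 1.0
        assert vessel_cost(v, F) == pytest.approx(expected, rel=1e-14)

    def test_diffusion_only(self):
        F = CostFunctional.sprouting(0.0, 0.0, 1.0, V_ref=1.0, l_ref=1.0,
                                     r_ref=1.0)
        v = _seed_tree().root
        v.x_p = np.array([0.0, 0.0, 0.0])
        v.x_d = np.array([1.0, 0.0, 0.0])
        assert vessel_cost(v, F) == pytest.approx(1.0, rel=1e-14)

    def test_coefficient_sum_enforced(self):
        with pytest.raises(ValueError):
            CostFunctional.sprouting(0.5, 0.5, 0.5, 1.0, 1.0, 1.0)

    def test_tree_cost_empty_and_additive(self, rng):
        F = CostFunctional.volumetric()
        assert tree_cost(None, F) == 0.0
        tree = build_random_tree(16, rng)  # 31 segments
        brute = 0.0
        for v in tree.vessels.values():
            brute += math.pi * np.linalg.norm(v.x_d - v.x_p) * v.r ** 2
        assert tree_cost(tree, F) == pytest.approx(brute, rel=1e-12)

    def test_two_identical_segments(self):
        F = CostFunctional.volumetric()
        tree = _seed_tree()
        single = tree_cost(tree, F)
        t2 = VascularTree.from_root([0, 0.5, 0.5], [0.2, 0.5, 0.5], r0=0.05,
                                    Q_in=1.0)
        v = t2.root
        extra = type(v)(id=99, x_p=v.x_p + [1, 0, 0], x_d=v.x_d + [1, 0, 0],
                        r=v.r)
        t2.vessels[99] = extra
        assert tree_cost(t2, F) == pytest.approx(2 * single, rel=1e-14)


class TestNeighbourhood:
    def test_single_vessel(self):
        tree = _seed_tree()
        for f_n in (0.1, 1.0, 10.0):
            assert neighbourhood(tree, [0.9, 0.9, 0.9], f_n) == [tree.root_id]

    def test_matches_brute_force(self, rng):
        tree = build_random_tree(8, rng)  # 15 vessels
        x = np.array([0.3, 0.6, 0.4])
        f_n = 3 / 15 ** (1 / 3)  # count of 3
        assert neighbourhood_size(15, f_n) == 3
        got = neighbourhood(tree, x, f_n)
        brute = sorted(
            tree.vessels,
            key=lambda vid: (_point_seg_dist(x, tree.vessels[vid]), vid),
        )[:3]
        assert got == brute

    def test_on_axis_vessel_first(self, rng):
        tree = build_random_tree(8, rng)
        v = tree.vessels[sorted(tree.vessels)[3]]
        on_axis = 0.5 * (v.x_p + v.x_d)
        assert neighbourhood(tree, on_axis, 1.0)[0] == v.id


def _point_seg_dist(x, v):
    u = v.x_d - v.x_p
    t = np.clip(np.dot(x - v.x_p, u) / np.dot(u, u), 0, 1)
    return float(np.linalg.norm(x - v.x_p - t * u))


class TestCandidatePoints:
    def test_single_candidate_is_centroid(self):
        a, b, c = np.eye(3)
        pts = candidate_bifurcation_points(a, b, c, 1)
        assert np.allclose(pts[0], (a + b + c) / 3, rtol=1e-15)

    def test_21_distinct_interior_points(self):
        a = np.array([0.0, 0.0, 0.0])
        b = np.array([1.0, 0.0, 0.0])
        c = np.array([0.2, 1.0, 0.0])
        pts = candidate_bifurcation_points(a, b, c, 21)
        assert len(pts) == 21
        assert len({tuple(p) for p in pts}) == 21
        # barycentric solve: strictly interior
        T = np.column_stack([b - a, c - a])
        for p in pts:
            lam = np.linalg.lstsq(T, p - a, rcond=None)[0]
            assert lam[0] > 0 and lam[1] > 0 and lam.sum() < 1

    def test_collinear_triangle_empty(self):
        a = np.array([0.0, 0.0, 0.0])
        b = np.array([1.0, 0.0, 0.0])
        c = np.array([2.0, 0.0, 0.0])
        assert len(candidate_bifurcation_points(a, b, c, 7)) == 0


class TestValidity:
    def _tree_and_stage(self, **kw):
        tree = _seed_tree()
        assign_terminal_flows(tree)
        rescale_radii(tree)
        return tree, StageConfig(N=1, **kw)

    def test_right_angle_daughters_pass(self):
        tree, stage = self._tree_and_stage(theta_min=30.0)
        ok, reason = is_valid_connection(tree, tree.root_id, [0.1, 0.5, 0.5],
                                         [0.1, 0.9, 0.5], stage, UNIT_BOX)
        assert ok, reason

    def test_phi_min_zero_always_passes_deviation(self):
        tree, stage = self._tree_and_stage(theta_min=0.0, phi_min=0.0)
        ok, reason = is_valid_connection(tree, tree.root_id, [0.1, 0.5, 0.5],
                                         [0.12, 0.52, 0.5], stage, UNIT_BOX)
        assert reason != "angle"

    def test_outside_domain(self):
        tree, stage = self._tree_and_stage()
        ok, reason = is_valid_connection(tree, tree.root_id, [0.1, 0.5, 0.5],
                                         [0.5, 1.8, 0.5], stage, UNIT_BOX)
        assert not ok and reason == "outside-domain"

    def test_angle_constraint_rejects(self):
        tree, stage = self._tree_and_stage(theta_min=60.0)
        # nearly parallel daughters
        ok, reason = is_valid_connection(tree, tree.root_id, [0.1, 0.5, 0.5],
                                         [0.21, 0.505, 0.5], stage, UNIT_BOX)
        assert not ok and reason == "angle"

    def test_symmetry_constraint(self, rng):
        tree = build_random_tree(8, rng)
        stage = StageConfig(N=1, delta=0.99)
        # an extremely asymmetric insertion: tiny terminal flow vs big subtree
        ok, reason = is_valid_connection(
            tree, tree.root_id,
            tree.root.x_p + 0.5 * (tree.root.x_d - tree.root.x_p),
            np.array([0.9, 0.9, 0.9]), stage, UNIT_BOX)
        assert not ok and reason in ("symmetry", "collision", "angle")


class TestTryInsert:
    def test_single_candidate(self):
        tree = _seed_tree()
        assign_terminal_flows(tree)
        rescale_radii(tree)
        stage = StageConfig(N=1, n_bif=1, f_n=10.0)
        ins = try_insert(tree, np.array([0.5, 0.8, 0.5]), stage, UNIT_BOX)
        assert ins is not None
        assert ins.parent_id == tree.root_id
        assert ins.dF > 0

    def test_matches_brute_force_argmin(self, rng):
        tree = build_random_tree(3, rng)  # 5 vessels
        stage = StageConfig(N=1, n_bif=7, f_n=100.0, theta_min=0.0)
        x_new = np.array([0.55, 0.35, 0.65])
        ins = try_insert(tree, x_new, stage, UNIT_BOX)
        assert ins is not None
        # exhaustive enumeration through the object model
        F = CostFunctional.volumetric()
        base = tree_cost(tree, F)
        best = None
        for pid in sorted(tree.vessels):
            v = tree.vessels[pid]
            for idx, bif in enumerate(
                candidate_bifurcation_points(v.x_p, v.x_d, x_new, 7)
            ):
                ok, _ = is_valid_connection(tree, pid, bif, x_new, stage,
                                            UNIT_BOX)
                if not ok:
                    continue
                trial = tree.copy()
                add_terminal(trial, pid, bif, x_new)
                assign_terminal_flows(trial)
                rescale_radii(trial)
                key = (tree_cost(trial, F) - base, pid, idx)
                if best is None or key < best:
                    best = key
        assert best is not None
        assert ins.parent_id == best[1]
        assert ins.candidate_index == best[2]
        assert ins.dF == pytest.approx(best[0], rel=1e-10)

    def test_equal_cost_tie_breaks_on_parent_id(self):
        # mirror-symmetric daughters about y = 0.5 give bitwise-equal dF
        tree = _seed_tree()
        add_terminal(tree, tree.root_id, [0.1875, 0.5, 0.5], [0.5, 0.75, 0.5])
        sib = [v.id for v in tree.vessels.values()
               if v.is_terminal and v.x_d[1] == 0.5][0]
        add_terminal(tree, sib, [0.19375, 0.5, 0.5], [0.5, 0.25, 0.5])
        assign_terminal_flows(tree)
        rescale_radii(tree)
        mirrored = [v.id for v in tree.vessels.values()
                    if v.is_terminal and v.x_d[1] != 0.5]
        stage = StageConfig(N=1, n_bif=1, f_n=100.0, theta_min=0.0)
        ins = try_insert(tree, np.array([0.75, 0.5, 0.5]), stage, UNIT_BOX)
        assert ins is not None
        if ins.parent_id in mirrored:
            assert ins.parent_id == min(mirrored)

    def test_none_when_nothing_valid(self):
        tree = _seed_tree()
        assign_terminal_flows(tree)
        rescale_radii(tree)
        stage = StageConfig(N=1, n_bif=1, theta_min=179.9)
        ins = try_insert(tree, np.array([0.5, 0.8, 0.5]), stage, UNIT_BOX)
        assert ins is None


class TestGrow:
    def test_zero_additions_identity(self):
        tree = _seed_tree()
        snapshot = {vid: v.r for vid, v in tree.vessels.items()}
        out = grow(tree, UNIT_BOX, StageConfig(N=0, seed=1))
        assert out is tree and len(tree.vessels) == 1
        assert {vid: v.r for vid, v in tree.vessels.items()} == snapshot

    def test_terminal_count(self):
        tree = _seed_tree()
        grow(tree, UNIT_BOX, StageConfig(N=49, seed=2))
        assert tree.n_terminals == 50
        tree.validate()

    def test_deterministic(self):
        results = []
        for _ in range(2):
            tree = _seed_tree()
            grow(tree, UNIT_BOX, StageConfig(N=40, seed=3))
            results.append(sorted(
                (tuple(v.x_p), tuple(v.x_d), v.r) for v in tree.vessels.values()
            ))
        assert results[0] == results[1]

    def test_df_matches_full_recompute(self, rng):
        tree = build_random_tree(6, rng)
        stage = StageConfig(N=1, n_bif=3, f_n=10.0)
        F = CostFunctional.volumetric()
        x_new = np.array([0.25, 0.7, 0.3])
        ins = try_insert(tree, x_new, stage, UNIT_BOX)
        assert ins is not None
        before = tree_cost(tree, F)
        trial = tree.copy()
        add_terminal(trial, ins.parent_id, ins.x_bif, x_new)
        assign_terminal_flows(trial)
        rescale_radii(trial)
        assert ins.dF == pytest.approx(tree_cost(trial, F) - before, rel=1e-10)

    def test_no_overlaps_post_hoc(self):
        tree = _seed_tree()
        grow(tree, UNIT_BOX, StageConfig(N=99, seed=4))
        vessels = list(tree.vessels.values())
        for a, b in itertools.combinations(vessels, 2):
            shared = any(np.array_equal(p, q)
                         for p in (a.x_p, a.x_d) for q in (b.x_p, b.x_d))
            if shared:
                continue
            assert _seg_seg_distance(a.x_p, a.x_d, b.x_p, b.x_d) > 0

    def test_volume_non_decreasing(self):
        tree = _seed_tree()
        vols = []
        for i in range(6):
            grow(tree, UNIT_BOX, StageConfig(N=10, seed=10 + i, name=f"c{i}"))
            vols.append(intravascular_volume(tree))
        assert all(b >= a for a, b in zip(vols, vols[1:]))

    def test_growth_error_when_impossible(self):
        tree = _seed_tree()
        stage = StageConfig(N=1, theta_min=179.99, relax_floor=0.5,
                            max_attempts_per_terminal=30)
        with pytest.raises(GrowthError):
            grow(tree, UNIT_BOX, stage)


class TestRunStages:
    def test_single_stage_equals_grow(self):
        a = _seed_tree()
        run_stages(a, [StageConfig(N=20, seed=5)], domain=UNIT_BOX)
        b = _seed_tree()
        grow(b, UNIT_BOX, StageConfig(N=20, seed=5))
        assert sorted(tuple(v.x_d) for v in a.vessels.values()) == \
            sorted(tuple(v.x_d) for v in b.vessels.values())

    def test_stage_sequence_counts_and_tags(self):
        tree = _seed_tree()
        run_stages(tree, [StageConfig(N=16, seed=6, name="S2"),
                          StageConfig(N=34, seed=7, name="S3")],
                   domain=UNIT_BOX)
        assert tree.n_terminals == 51
        stages = {v.stage for v in tree.vessels.values()}
        assert {"S2", "S3"} <= stages

    def test_empty_stage_list_identity(self):
        tree = _seed_tree()
        out = run_stages(tree, [], domain=UNIT_BOX)
        assert out is tree and tree.n_segments == 1

    def test_missing_domain_rejected(self):
        with pytest.raises(ValueError):
            run_stages(_seed_tree(), [StageConfig(N=1)])
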