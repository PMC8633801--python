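import numpy as np
import pytest

from vasctree.dcco_growth import StageConfig, grow
from vasctree.domain_geometry import BoxDomain, partition_axis_aligned
from vasctree.pdcco import (
    InsertionRecord,
    MergeError,
    grow_subdomain,
    merge,
    merged_terminal_count,
    partition_parents,
    pdcco_pipeline,
    split_counts,
    subdomain_flow_conditions,
)
from vasctree.vessel_tree import VascularTree, assign_terminal_flows


@pytest.fixture(scope="module")
def baseline():
    """Shared 60-terminal baseline in the 4x1x1 box with its partition."""
    domain = BoxDomain([0, 0, 0], [4, 1, 1], seed=0)
    tree = VascularTree.from_root([0, 0.5, 0.5], [0.4, 0.5, 0.5],
                                  r0=0.075, Q_in=0.002)
    grow(tree, domain, StageConfig(N=59, seed=1, name="base"))
    partition = partition_axis_aligned(domain, (4, 1, 1))
    return domain, partition, tree


class TestPartitionParents:
    def test_midpoint_rule(self, baseline):
        _, partition, tree = baseline
        for idx in range(4):
            for vid in partition_parents(tree, partition, idx):
                assert partition.label(tree.vessels[vid].midpoint) == idx

    def test_disjoint_and_bounded(self, baseline):
        _, partition, tree = baseline
        sets = [partition_parents(tree, partition, i) for i in range(4)]
        total = sum(len(s) for s in sets)
        assert total <= tree.n_segments
        for i in range(4):
            for j in range(i + 1, 4):
                assert not (sets[i] & sets[j])
        # exhaustive classification oracle
        for v in tree.vessels.values():
            label = partition.label(v.midpoint)
            for i, s in enumerate(sets):
                assert (v.id in s) == (label == i)

    def test_empty_subdomain_errors(self):
        domain = BoxDomain([0, 0, 0], [4, 1, 1], seed=0)
        partition = partition_axis_aligned(domain, (4, 1, 1))
        tree = VascularTree.from_root([0, 0.5, 0.5], [0.2, 0.5, 0.5],
                                      r0=0.075, Q_in=0.002)
        with pytest.raises(ValueError, match="subdomain 3"):
            partition_parents(tree, partition, 3)


class TestFlowConditions:
    def test_conservation_exact(self, baseline):
        _, partition, tree = baseline
        frozen, free = subdomain_flow_conditions(tree, partition, 1)
        q_part = tree.Q_in - sum(frozen.values())
        assert q_part > 0
        assert sum(frozen.values()) + q_part == pytest.approx(tree.Q_in,
                                                              rel=1e-15)
        assert set(frozen) | set(free) == set(tree.terminal_ids())

    def test_no_outside_terminals_is_uniform(self):
        domain = BoxDomain([0, 0, 0], [1, 1, 1], seed=0)
        tree = VascularTree.from_root([0, 0.5, 0.5], [0.2, 0.5, 0.5],
                                      r0=0.05, Q_in=1.0)
        grow(tree, domain, StageConfig(N=9, seed=2))
        partition = partition_axis_aligned(domain, (1, 1, 1))
        frozen, free = subdomain_flow_conditions(tree, partition, 0)
        assert frozen == {}
        assert len(free) == tree.n_terminals

    def test_equal_subdomains_quarter_flow(self, baseline):
        _, partition, tree = baseline
        parts = [tree.Q_in - sum(subdomain_flow_conditions(tree, partition, i)[0].values())
                 for i in range(4)]
        # uniformly grown baseline spreads terminals roughly evenly
        for q in parts:
            assert q == pytest.approx(tree.Q_in / 4, rel=0.8)
        assert sum(parts) == pytest.approx(tree.Q_in, rel=1e-12)


class TestGrowSubdomain:
    def test_zero_additions(self, baseline):
        _, partition, tree = baseline
        out, records = grow_subdomain(tree, partition, 0,
                                      StageConfig(N=0, seed=3))
        assert records == []
        assert out.n_terminals == tree.n_terminals
        assert out is not tree

    def test_record_count_and_order(self, baseline):
        _, partition, tree = baseline
        out, records = grow_subdomain(tree, partition, 2,
                                      StageConfig(N=15, seed=4), seed=7)
        assert len(records) == 15
        assert [r.sequence for r in records] == list(range(15))
        assert all(r.subdomain == 2 for r in records)
        assert out.n_terminals == tree.n_terminals + 15

    def test_outside_topology_untouched(self, baseline):
        _, partition, tree = baseline
        out, _ = grow_subdomain(tree, partition, 1,
                                StageConfig(N=10, seed=5), seed=7)
        outside = [v for v in tree.vessels.values()
                   if partition.label(v.midpoint) != 1]
        for v in outside:
            assert v.id in out.vessels
            w = out.vessels[v.id]
            assert np.array_equal(v.x_p, w.x_p) and np.array_equal(v.x_d, w.x_d)

    def test_independent_of_order(self, baseline):
        _, partition, tree = baseline
        a1, r1 = grow_subdomain(tree, partition, 0, StageConfig(N=8, seed=6),
                                seed=9)
        b2, r2 = grow_subdomain(tree, partition, 3, StageConfig(N=8, seed=6),
                                seed=9)
        a1b, r1b = grow_subdomain(tree, partition, 0, StageConfig(N=8, seed=6),
                                  seed=9)
        assert [tuple(r.x_new) for r in r1] == [tuple(r.x_new) for r in r1b]
        assert [tuple(r.x_new) for r in r1] != [tuple(r.x_new) for r in r2]

    def test_candidate_points_stay_in_subdomain(self, baseline):
        _, partition, tree = baseline
        _, records = grow_subdomain(tree, partition, 2,
                                    StageConfig(N=12, seed=8), seed=11)
        for r in records:
            assert partition.label(r.x_new) == 2


class TestMerge:
    def test_zero_records_identity(self, baseline):
        _, _, tree = baseline
        merged = merge(tree, [[], [], []])
        assert merged.n_terminals == tree.n_terminals
        for vid, v in tree.vessels.items():
            assert merged.vessels[vid].r == pytest.approx(v.r, rel=1e-12)

    def test_merge_counts(self, baseline):
        _, partition, tree = baseline
        lists = [grow_subdomain(tree, partition, i, StageConfig(N=10, seed=20 + i),
                                seed=13)[1] for i in range(4)]
        merged = merge(tree, lists)
        assert merged.n_terminals == tree.n_terminals + 40
        merged.validate()

    def test_merged_topology_isomorphic_to_subtree(self, baseline):
        _, partition, tree = baseline
        sub, records = grow_subdomain(tree, partition, 1,
                                      StageConfig(N=12, seed=30), seed=17)
        merged = merge(tree, [records])
        sub_keys = {(tuple(v.x_p), tuple(v.x_d)) for v in sub.vessels.values()}
        merged_keys = {(tuple(v.x_p), tuple(v.x_d))
                       for v in merged.vessels.values()}
        assert merged_keys == sub_keys

    def test_cross_list_order_invariance(self, baseline):
        _, partition, tree = baseline
        lists = [grow_subdomain(tree, partition, i, StageConfig(N=8, seed=40 + i),
                                seed=19)[1] for i in range(4)]
        a = merge(tree, lists)
        b = merge(tree, list(reversed(lists)))
        ka = sorted((tuple(v.x_p), tuple(v.x_d), round(v.r, 15))
                    for v in a.vessels.values())
        kb = sorted((tuple(v.x_p), tuple(v.x_d), round(v.r, 15))
                    for v in b.vessels.values())
        assert ka == kb

    def test_parent_midpoint_in_record_subdomain(self, baseline):
        # no baseline vessel bifurcates into two subdomains
        _, partition, tree = baseline
        for i in range(4):
            _, records = grow_subdomain(tree, partition, i,
                                        StageConfig(N=6, seed=50 + i), seed=23)
            base_keys = {(tuple(v.x_p), tuple(v.x_d)): v.id
                         for v in tree.vessels.values()}
            for r in records:
                key = (tuple(r.parent_x_p), tuple(r.parent_x_d))
                if key in base_keys:  # original baseline vessel
                    mid = 0.5 * (r.parent_x_p + r.parent_x_d)
                    assert partition.label(mid) == i

    def test_corrupted_record_errors(self, baseline):
        _, _, tree = baseline
        bad = InsertionRecord(
            x_new=np.array([0.5, 0.5, 0.5]), x_bif=np.array([0.4, 0.5, 0.5]),
            parent_x_p=np.array([9.0, 9.0, 9.0]),
            parent_x_d=np.array([9.5, 9.0, 9.0]), sequence=0, subdomain=0)
        with pytest.raises(MergeError, match="subdomain 0"):
            merge(tree, [[bad]])

    def test_flow_conservation_in_merged(self, baseline):
        _, partition, tree = baseline
        lists = [grow_subdomain(tree, partition, i, StageConfig(N=5, seed=60 + i),
                                seed=29)[1] for i in range(4)]
        merged = merge(tree, lists)
        total = sum(merged.vessels[t].q_out for t in merged.terminal_ids())
        assert total == pytest.approx(merged.Q_in, rel=1e-12)
        g = merged.gamma
        for v in merged.vessels.values():
            if not v.is_terminal:
                cl, cr = (merged.vessels[c] for c in v.children)
                assert abs(v.r ** g - cl.r ** g - cr.r ** g) / v.r ** g < 1e-10


class TestPipeline:
    def test_degenerate_single_partition(self):
        domain = BoxDomain([0, 0, 0], [1, 1, 1], seed=0)
        partition = partition_axis_aligned(domain, (1, 1, 1))
        res = pdcco_pipeline(
            domain, partition, StageConfig(N=19, seed=1, name="base"),
            [StageConfig(N=15, seed=2, name="sub")],
            inlet=dict(x_p=[0, 0.5, 0.5], x_d=[0.2, 0.5, 0.5], r0=0.05,
                       Q_in=1.0), seed=3)
        assert res.base.n_terminals == 20
        assert res.merged.n_terminals == 35

    def test_serial_equals_concurrent(self):
        domain = BoxDomain([0, 0, 0], [4, 1, 1], seed=0)
        partition = partition_axis_aligned(domain, (4, 1, 1))
        kwargs = dict(
            inlet=dict(x_p=[0, 0.5, 0.5], x_d=[0.4, 0.5, 0.5], r0=0.075,
                       Q_in=0.002), seed=5)
        stages = lambda: [StageConfig(N=10, seed=0, name=f"s{i}")
                          for i in range(4)]
        a = pdcco_pipeline(domain, partition, StageConfig(N=29, seed=4),
                           stages(), parallel=False, **kwargs)
        b = pdcco_pipeline(domain, partition, StageConfig(N=29, seed=4),
                           stages(), parallel=True, **kwargs)
        for vid, v in a.merged.vessels.items():
            w = b.merged.vessels[vid]
            assert np.array_equal(v.x_p, w.x_p)
            assert np.array_equal(v.x_d, w.x_d)
            assert v.r == w.r

    def test_stage_count_mismatch(self):
        domain = BoxDomain([0, 0, 0], [1, 1, 1], seed=0)
        partition = partition_axis_aligned(domain, (2, 1, 1))
        with pytest.raises(ValueError):
            pdcco_pipeline(domain, partition, StageConfig(N=5),
                           [StageConfig(N=1)],
                           inlet=dict(x_p=[0, 0.5, 0.5], x_d=[0.2, 0.5, 0.5],
                                      r0=0.05, Q_in=1.0))


class TestBookkeeping:
    def test_merged_terminal_count(self):
        assert merged_terminal_count(500, [200] * 4) == 1300
        assert merged_terminal_count(2500, [625] * 4) == 5000
        assert merged_terminal_count(200, [400] * 8) == 3400

    def test_split_counts(self):
        assert split_counts(250, 4) == [62, 62, 62, 64]
        assert split_counts(8, 4) == [2, 2, 2, 2]
        assert sum(split_counts(97, 8)) == 97
        with pytest.raises(ValueError):
            split_counts(10, 0)
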