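import numpy as np
import pytest

from cxlineage.backbone import (BackboneParams, Fragment, extract_backbone,
                                fragment_at_branchpoints, map_connectors_to_nodes,
                                prune_twigs, select_fragments, trim_distal_fragments)
from cxlineage.io import SkeletonGraph

from .oracles import oracle_backbone_nodes, random_skeleton


def path_skeleton(n, spacing=8.0):
    """Straight path of n nodes along +x, ids 1..n."""
    xyz = np.column_stack([np.arange(n) * spacing, np.zeros(n), np.zeros(n)])
    parents = np.concatenate([[-1], np.arange(1, n)])
    return SkeletonGraph("p", np.arange(1, n + 1), parents, xyz,
                         np.full(n, 30.0), soma_node=1)


def with_twig(skel, attach_id, n_twig, spacing=8.0):
    """Attach a straight side twig of n_twig nodes at node ``attach_id``."""
    base = skel.position_of(attach_id)
    start = skel.n_nodes + 1
    ids = np.concatenate([skel.node_ids, np.arange(start, start + n_twig)])
    tw_par = np.concatenate([[attach_id], np.arange(start, start + n_twig - 1)])
    parents = np.concatenate([skel.parent_ids, tw_par])
    tw_xyz = base + np.column_stack([np.zeros(n_twig),
                                     (np.arange(n_twig) + 1) * spacing,
                                     np.zeros(n_twig)])
    xyz = np.concatenate([skel.xyz, tw_xyz])
    return SkeletonGraph(skel.neuron_id, ids, parents, xyz,
                         np.full(len(ids), 30.0), soma_node=skel.soma_node)


class TestPruneTwigs:
    def test_small_connectorless_twig_removed(self):
        skel = with_twig(path_skeleton(200), attach_id=100, n_twig=10)
        out = prune_twigs(skel, {}, BackboneParams())
        assert set(out.node_ids) == set(range(1, 201))

    def test_twig_with_connector_retained(self):
        skel = with_twig(path_skeleton(200), attach_id=100, n_twig=10)
        conn = skel.position_of(205)[None]          # a T-bar on the twig
        cmap = map_connectors_to_nodes(skel, conn)
        out = prune_twigs(skel, cmap, BackboneParams())
        assert out.n_nodes == skel.n_nodes

    def test_unbranched_skeleton_unchanged(self):
        skel = path_skeleton(10)
        out = prune_twigs(skel, {}, BackboneParams())
        assert out.n_nodes == 10

    @pytest.mark.parametrize("n_twig,survives", [(14, False), (15, True), (20, True)])
    def test_node_count_boundary(self, n_twig, survives):
        skel = with_twig(path_skeleton(200), attach_id=100, n_twig=n_twig)
        out = prune_twigs(skel, {}, BackboneParams())
        assert (out.n_nodes == skel.n_nodes) is survives

    def test_nested_twigs_removed_to_fixpoint(self):
        skel = with_twig(path_skeleton(200), attach_id=100, n_twig=10)
        skel = with_twig(skel, attach_id=205, n_twig=5)   # twig on the twig
        out = prune_twigs(skel, {}, BackboneParams())
        assert set(out.node_ids) == set(range(1, 201))


class TestFragmentation:
    def test_y_skeleton_three_fragments(self):
        skel = with_twig(path_skeleton(40), attach_id=20, n_twig=20)
        frags = fragment_at_branchpoints(skel)
        assert len(frags) == 3
        # branch point 20 duplicated into every incident fragment
        assert sum(20 in f.node_ids for f in frags) == 3

    def test_unbranched_path_single_fragment(self):
        frags = fragment_at_branchpoints(path_skeleton(50))
        assert len(frags) == 1
        assert len(frags[0].node_ids) == 50

    def test_h_skeleton_five_fragments(self):
        skel = with_twig(path_skeleton(60), attach_id=20, n_twig=20)
        skel = with_twig(skel, attach_id=40, n_twig=20)
        frags = fragment_at_branchpoints(skel)
        assert len(frags) == 5

    def test_fragments_partition_edges(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            skel, _ = random_skeleton(rng, max_nodes=40)
            frags = fragment_at_branchpoints(skel)
            n_edges = sum(len(f.node_ids) - 1 for f in frags)
            assert n_edges == skel.n_nodes - 1


def frag(length, n_conn, origin=0.0):
    """Straight fragment of given cable length along x starting at origin."""
    n = max(int(length // 100) + 1, 2)
    xs = np.linspace(origin, origin + length, n)
    pts = np.column_stack([xs, np.zeros(n), np.zeros(n)])
    f = Fragment.from_path(np.arange(len(pts)), pts)
    f.connector_count = n_conn
    return f


class TestSelectFragments:
    def test_large_fragment_kept_regardless_of_connectors(self):
        kept = select_fragments([frag(3000, 50)], BackboneParams())
        assert len(kept) == 1

    def test_fragment_below_small_threshold_discarded(self):
        kept = select_fragments([frag(5000, 0), frag(60, 0)], BackboneParams())
        assert len(kept) == 1

    def test_connector_dense_fragment_discarded(self):
        # 12 connectors on 1000 nm: 12 >= 0.01 * 1000
        kept = select_fragments([frag(5000, 0), frag(1000, 12)], BackboneParams())
        assert len(kept) == 1

    def test_relative_length_rule_default_reading(self):
        # 1000 < 10000 / 2.5 -> secondary fragment discarded
        kept = select_fragments([frag(10000, 0), frag(1000, 2)], BackboneParams())
        assert [f.cable_length for f in kept] == [10000.0]
        # a 5000 nm secondary fragment passes 5000 >= 10000 / 2.5 but is
        # already kept by the large rule; use 2400 nm: 2400 < 4000 -> dropped
        kept = select_fragments([frag(10000, 0), frag(2400, 2)], BackboneParams())
        assert len(kept) == 1

    def test_relative_length_rule_literal_reading(self):
        p = BackboneParams(literal_relative_rule=True)
        kept = select_fragments([frag(10000, 0), frag(2400, 2)], p)
        assert len(kept) == 1          # the literal reading keeps only (a)-fragments

    def test_empty_input(self):
        assert select_fragments([], BackboneParams()) == []

    def test_monotone_in_large_threshold(self):
        """Raising the large-fragment threshold never adds fragments."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            skel, conn = random_skeleton(rng)
            cmap = map_connectors_to_nodes(skel, conn)
            frags = fragment_at_branchpoints(skel, cmap)
            lo = select_fragments(frags, BackboneParams())
            hi = select_fragments(frags, BackboneParams(large_fragment_min_len=6000))
            lo_ids = {tuple(f.node_ids) for f in lo}
            assert {tuple(f.node_ids) for f in hi} <= lo_ids


class TestTrimDistal:
    def test_far_satellite_discarded(self):
        kept = trim_distal_fragments([frag(10000, 0), frag(500, 0, origin=22000)],
                                     BackboneParams())
        assert len(kept) == 1

    def test_touching_fragment_kept(self):
        kept = trim_distal_fragments([frag(10000, 0), frag(500, 0, origin=10000)],
                                     BackboneParams())
        assert len(kept) == 2

    def test_near_one_end_only_is_enough(self):
        # 4000 nm past the far end, 24000 from the near end
        kept = trim_distal_fragments([frag(10000, 0), frag(500, 0, origin=14000)],
                                     BackboneParams())
        assert len(kept) == 2

    def test_single_fragment_unchanged(self):
        f = frag(100, 0)
        assert trim_distal_fragments([f], BackboneParams()) == [f]


class TestExtractBackbone:
    def test_planted_main_path_recovered(self, small_brain):
        p = BackboneParams()
        from cxlineage.synth import connector_positions_for
        for nid, skel in small_brain.skeletons.items():
            res = extract_backbone(skel, connector_positions_for(
                small_brain.connectors, nid), p)
            assert res.node_ids == set(small_brain.truth.backbone_nodes[nid])

    def test_all_tiny_fragments_give_empty_backbone_with_warning(self):
        skel = path_skeleton(5)          # 32 nm of cable
        with pytest.warns(UserWarning, match="empty backbone"):
            res = extract_backbone(skel, None, BackboneParams())
        assert res.node_ids == set()

    def test_backbone_is_subset_of_skeleton(self):
        rng = np.random.default_rng(3)
        import warnings
        for _ in range(50):
            skel, conn = random_skeleton(rng)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = extract_backbone(skel, conn, BackboneParams())
            assert res.node_ids <= set(int(n) for n in skel.node_ids)

    def test_idempotent_on_clean_tract(self, small_brain):
        from cxlineage.synth import connector_positions_for
        p = BackboneParams()
        nid, skel = next(iter(small_brain.skeletons.items()))
        res = extract_backbone(skel, connector_positions_for(
            small_brain.connectors, nid), p)
        again = extract_backbone(skel.subgraph(res.node_ids), None, p)
        largest = max(res.fragments, key=lambda f: f.cable_length)
        assert set(int(n) for n in largest.node_ids) <= again.node_ids

    def test_matches_brute_force_oracle(self):
        """Rule-by-rule agreement with an independent implementation."""
        import warnings
        rng = np.random.default_rng(99)
        p = BackboneParams()
        for _ in range(200):
            skel, conn = random_skeleton(rng)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = extract_backbone(skel, conn, p)
            assert res.node_ids == oracle_backbone_nodes(skel, conn, p)


def test_params_validated():
    with pytest.raises(ValueError):
        BackboneParams(twig_node_max=0)
    with pytest.raises(ValueError):
        BackboneParams(connector_density_max=1.5)
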