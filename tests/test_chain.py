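"""DAG construction, heaviest-path DP, and iterative block extraction."""

import numpy as np
import pytest

from synchain.chain import (
    build_dag,
    component_key,
    extract_blocks,
    heaviest_path,
    topological_order,
)
from synchain.model import (
    AnchorBlock,
    GenomeSide,
    Resolution,
    SyntenyBlock,
    is_syntenic,
)

from _oracles import adjacency_matrix, max_chain_weight, random_anchors


def colinear(sizes, gap=50, chrom_q="q", chrom_t="t", start_id=0):
    """Perfectly colinear + strand anchors with the given sizes."""
    anchors, q = [], 0
    t = 7  # arbitrary target offset
    for i, size in enumerate(sizes):
        anchors.append(
            AnchorBlock(
                GenomeSide(chrom_q, q, q + size),
                GenomeSide(chrom_t, t, t + size),
                "+",
                id=start_id + i,
            )
        )
        q += size + gap
        t += size + gap
    return anchors


class TestBuildDag:
    def test_empty_input_gives_empty_graph(self):
        g = build_dag([], Resolution(0, 100))
        assert len(g) == 0 and heaviest_path(g) is None

    def test_edge_exists_iff_within_distance(self):
        a, b = colinear([100, 100], gap=60)
        g_wide = build_dag([a, b], Resolution(0, 100))
        g_tight = build_dag([a, b], Resolution(0, 50))
        assert [u.id for u in g_wide.successors(a)] == [b.id]
        assert list(g_tight.successors(a)) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_windowed_adjacency_matches_all_pairs_predicate(self, seed):
        """The pruned successor scan is exact w.r.t. the O(n^2) predicate matrix."""
        rng = np.random.default_rng(seed)
        anchors = random_anchors(rng, 40)
        res = Resolution(0, int(rng.integers(0, 500)))
        g = build_dag(anchors, res)
        oracle = adjacency_matrix(anchors, res)
        for a in anchors:
            assert {u.id for u in g.successors(a)} == oracle[a.id]

    def test_vertices_partitioned_by_chromosome_pair_and_strand(self):
        rng = np.random.default_rng(1)
        anchors = random_anchors(rng, 30)
        g = build_dag(anchors, Resolution(0, 1000))
        for key, verts in g.components.items():
            assert all(component_key(v) == key for v in verts)
        assert sum(len(v) for v in g.components.values()) == len(anchors)


class TestTopologicalOrder:
    def test_sorted_by_query_start(self):
        anchors = [
            AnchorBlock(GenomeSide("q", s, s + 10), GenomeSide("t", s, s + 10), "+", i)
            for i, s in enumerate([300, 0, 150])
        ]
        g = build_dag(anchors, Resolution(0, 1000))
        order = topological_order(g)
        starts = [g.by_id[i].query.start for i in order]
        assert starts == [0, 150, 300]

    def test_every_edge_goes_forward(self):
        rng = np.random.default_rng(5)
        anchors = random_anchors(rng, 50)
        g = build_dag(anchors, Resolution(0, 800))
        pos = {vid: k for k, vid in enumerate(topological_order(g))}
        for a in anchors:
            for b in g.successors(a):
                assert pos[a.id] < pos[b.id]

    def test_ties_broken_by_end_then_id(self):
        mk = lambda end, i: AnchorBlock(
            GenomeSide("q", 0, end), GenomeSide("t", 0, end), "+", i
        )
        g = build_dag([mk(30, 2), mk(20, 1), mk(20, 0)], Resolution(0, 10))
        assert topological_order(g) == [0, 1, 2]


class TestHeaviestPath:
    def test_single_vertex(self):
        (a,) = colinear([500])
        g = build_dag([a], Resolution(0, 10))
        path = heaviest_path(g)
        assert [v.id for v in path] == [a.id]
        assert g.weight[a.id] == 500

    def test_simple_chain_accumulates_all_sizes(self):
        anchors = colinear([100, 50, 200])
        g = build_dag(anchors, Resolution(0, 100))
        path = heaviest_path(g)
        assert [v.id for v in path] == [0, 1, 2]
        assert sum(v.size for v in path) == 350

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_enumeration(self, seed):
        """DP path weight equals the max over all chains found by brute force."""
        rng = np.random.default_rng(100 + seed)
        anchors = random_anchors(rng, int(rng.integers(1, 13)))
        res = Resolution(0, int(rng.integers(0, 600)))
        g = build_dag(anchors, res)
        path = heaviest_path(g)
        assert sum(v.size for v in path) == max_chain_weight(anchors, res)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_networkx_longest_path(self, seed):
        """Cross-check against networkx dag_longest_path on an edge-weighted graph."""
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(200 + seed)
        anchors = random_anchors(rng, 30)
        res = Resolution(0, int(rng.integers(50, 600)))
        G = nx.DiGraph()
        G.add_node("source")
        for a in anchors:
            G.add_edge("source", a.id, weight=a.size)
        for a in anchors:
            for b in anchors:
                if b.id != a.id and is_syntenic(a, b, res):
                    G.add_edge(a.id, b.id, weight=b.size)
        expected = nx.dag_longest_path_length(G, weight="weight")
        path = heaviest_path(build_dag(anchors, res))
        assert sum(v.size for v in path) == expected

    def test_tie_broken_by_smallest_position(self):
        a = AnchorBlock(GenomeSide("qB", 0, 100), GenomeSide("t", 0, 100), "+", 0)
        b = AnchorBlock(GenomeSide("qA", 50, 150), GenomeSide("t", 0, 100), "+", 1)
        g = build_dag([a, b], Resolution(0, 100))
        path = heaviest_path(g)
        assert [v.id for v in path] == [1]  # qA sorts before qB at equal weight


class TestExtractBlocks:
    def test_no_anchors_no_blocks(self):
        assert extract_blocks([], Resolution(0, 100)) == []

    def test_colinear_chain_emits_one_block_with_all_anchors(self):
        anchors = colinear([100] * 20, gap=10)
        blocks = extract_blocks(anchors, Resolution(0, 10**9))
        assert len(blocks) == 1
        assert blocks[0].anchor_ids == tuple(range(20))

    def test_translocation_splits_into_one_block_per_chromosome_pairing(self):
        left = colinear([100] * 3, chrom_t="t1", start_id=0)
        # interleave a second chain against another target chromosome
        right = [
            AnchorBlock(
                GenomeSide("q", a.query.start + 50, a.query.end + 50),
                GenomeSide("t2", a.target.start, a.target.end),
                "+",
                id=3 + i,
            )
            for i, a in enumerate(colinear([100] * 3))
        ]
        blocks = extract_blocks(left + right, Resolution(0, 10**9))
        assert len(blocks) == 2
        by_target = {b.target_span.chrom: b.anchor_ids for b in blocks}
        assert by_target == {"t1": (0, 1, 2), "t2": (3, 4, 5)}

    def test_short_paths_filtered_by_min_block_size(self):
        anchors = colinear([100] * 3, gap=10)  # query span 320
        assert extract_blocks(anchors, Resolution(321, 10**9)) == []
        assert len(extract_blocks(anchors, Resolution(320, 10**9))) == 1

    def test_duplicated_anchors_yield_singleton_blocks(self):
        anchors = [
            AnchorBlock(GenomeSide("q", 0, 100), GenomeSide("t", 0, 100), "+", i)
            for i in range(6)
        ]
        blocks = extract_blocks(anchors, Resolution(0, 10**9))
        assert [len(b) for b in blocks] == [1] * 6
        assert sorted(b.anchors[0].id for b in blocks) == list(range(6))

    def test_each_vertex_used_at_most_once(self):
        rng = np.random.default_rng(11)
        anchors = random_anchors(rng, 60)
        blocks = extract_blocks(anchors, Resolution(0, 400))
        seen = [i for b in blocks for i in b.anchor_ids]
        assert len(seen) == len(set(seen))

    @pytest.mark.parametrize("seed", range(8))
    def test_greedy_dominance_weights_non_increasing_per_component(self, seed):
        rng = np.random.default_rng(400 + seed)
        anchors = random_anchors(rng, 40)
        res = Resolution(0, int(rng.integers(100, 600)))
        g = build_dag(anchors, res)
        per_comp: dict = {}
        for key in sorted(g.components):
            weights = []
            while True:
                path = heaviest_path(g, component=key)
                if path is None:
                    break
                weights.append(sum(v.size for v in path))
                g.remove(v.id for v in path)
            assert weights == sorted(weights, reverse=True)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(21)
        anchors = random_anchors(rng, 50)
        res = Resolution(0, 300)
        reference = extract_blocks(anchors, res)
        shuffled = list(anchors)
        rng.shuffle(shuffled)
        assert extract_blocks(shuffled, res) == reference

    def test_emitted_blocks_satisfy_all_invariants(self):
        rng = np.random.default_rng(31)
        anchors = random_anchors(rng, 80)
        res = Resolution(30, 350)
        for blk in extract_blocks(anchors, res):
            # re-validates properties (i)-(iv) and the gap constraint
            SyntenyBlock.from_anchors(blk.anchors, res)
            assert blk.query_span.length >= res.min_block_size
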