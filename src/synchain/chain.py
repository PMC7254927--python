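"""DAG construction over anchors and iterative heaviest-path extraction.

The chaining graph has one vertex per gapless anchor and an edge a -> b
whenever :func:`~synchain.model.is_syntenic` holds, i.e. b can directly
follow a in a chain at the chosen resolution.  Because every edge increases
the query start coordinate, the graph is acyclic and the query order is a
topological order.  Within each (query chromosome, target chromosome,
strand) component the algorithm repeatedly

1. initialises every vertex weight to its anchor size,
2. sweeps the vertices in topological order, relaxing each outgoing edge:
   a successor's weight becomes ``w(v) + size(successor)`` when that is
   strictly greater, with the predecessor stored for backtracking,
3. backtracks from the maximum-weight vertex to recover the heaviest chain,
4. emits the chain as a synteny block if its query span reaches
   ``min_block_size``, removes its vertices, and repeats; otherwise the
   component is finished.

The DP state is recomputed from scratch each round: removing the extracted
vertices invalidates accumulated weights, and per-component recomputation is
cheap.  All tie-breaks (maximum-weight vertex, equal-weight relaxations) are
deterministic: a candidate equal to the current weight never replaces it,
and the maximum vertex is the smallest (query chromosome, query start, id)
among the heaviest.

Successor enumeration is pruned exactly: a successor of ``v`` must have its
query start in ``[v.query.end, v.query.end + max_anchor_distance]`` — any
vertex outside that window fails the query-gap clause of the predicate — so
adjacency is generated lazily from a bisected window of the per-component
list sorted by query start, and dense inputs never materialise O(n^2) edges.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from typing import Iterable, Iterator, Sequence

from .model import AnchorBlock, Resolution, SyntenyBlock, is_syntenic

ComponentKey = tuple[str, str, str]  # (query chrom, target chrom, strand)


def component_key(a: AnchorBlock) -> ComponentKey:
    return (a.query.chrom, a.target.chrom, a.strand)


def _vertex_order(a: AnchorBlock) -> tuple[str, int, int, int]:
    return (a.query.chrom, a.query.start, a.query.end, a.id)


class ChainGraph:
    """The chaining DAG: vertices, lazy syntenic adjacency, and DP state.

    Vertices are partitioned into (query chrom, target chrom, strand)
    components; edges never cross components.  An *active set* supports the
    extraction loop: removed vertices disappear from adjacency and DP.
    ``weight`` and ``parent`` hold the state of the most recent DP sweep.
    """

    def __init__(self, anchors: Iterable[AnchorBlock], resolution: Resolution):
        self.resolution = resolution
        self.by_id: dict[int, AnchorBlock] = {}
        self.components: dict[ComponentKey, list[AnchorBlock]] = {}
        for a in anchors:
            if a.id in self.by_id:
                raise ValueError(f"duplicate anchor id {a.id}")
            self.by_id[a.id] = a
            self.components.setdefault(component_key(a), []).append(a)
        for verts in self.components.values():
            verts.sort(key=_vertex_order)
        self._starts: dict[ComponentKey, list[int]] = {
            key: [v.query.start for v in verts]
            for key, verts in self.components.items()
        }
        self.active: set[int] = set(self.by_id)
        self.weight: dict[int, int] = {}
        self.parent: dict[int, int | None] = {}

    def __len__(self) -> int:
        return len(self.by_id)

    @property
    def vertices(self) -> list[AnchorBlock]:
        return sorted(self.by_id.values(), key=_vertex_order)

    def active_vertices(self, key: ComponentKey | None = None) -> list[AnchorBlock]:
        """Active vertices (of one component, or all) in topological order."""
        if key is not None:
            return [v for v in self.components.get(key, []) if v.id in self.active]
        return [v for v in self.vertices if v.id in self.active]

    def successors(self, v: AnchorBlock) -> Iterator[AnchorBlock]:
        """Active vertices u with is_syntenic(v, u) at the build resolution.

        Candidates are scanned from the sorted-by-query-start window
        [v.query.end, v.query.end + d_max]; the window bound is exact for the
        query-gap clause, and the full predicate is applied to each candidate.
        """
        key = component_key(v)
        verts = self.components[key]
        starts = self._starts[key]
        lo = bisect_left(starts, v.query.end)
        hi = bisect_right(starts, v.query.end + self.resolution.max_anchor_distance)
        for u in verts[lo:hi]:
            if u.id in self.active and is_syntenic(v, u, self.resolution):
                yield u

    def remove(self, ids: Iterable[int]) -> None:
        """Deactivate vertices (and implicitly every incident edge)."""
        self.active.difference_update(ids)


def build_dag(anchors: Sequence[AnchorBlock], resolution: Resolution) -> ChainGraph:
    """Construct the chaining DAG over the given anchors."""
    return ChainGraph(anchors, resolution)


def topological_order(g: ChainGraph) -> list[int]:
    """Vertex ids sorted by (query chrom, query start, query end, id).

    Valid because every edge strictly increases the query start coordinate
    within a chromosome, and edges never cross chromosomes.
    """
    return [v.id for v in g.active_vertices()]


def heaviest_path(
    g: ChainGraph, component: ComponentKey | None = None
) -> list[AnchorBlock] | None:
    """Run the DP and return the maximum-weight chain among active vertices.

    With ``component`` given, only that component is considered; otherwise
    the heaviest chain over the whole graph is returned.  Returns ``None``
    when no active vertex exists.  After the call, ``g.weight``/``g.parent``
    hold the DP labels of the swept vertices.
    """
    keys = [component] if component is not None else sorted(g.components)
    best_id: int | None = None
    for key in keys:
        verts = g.active_vertices(key)
        for v in verts:
            g.weight[v.id] = v.size
            g.parent[v.id] = None
        for v in verts:  # query order == topological order
            wv = g.weight[v.id]
            for u in g.successors(v):
                candidate = wv + u.size
                if candidate > g.weight[u.id]:
                    g.weight[u.id] = candidate
                    g.parent[u.id] = v.id
        for v in verts:
            if best_id is None:
                best_id = v.id
                continue
            wb, wv = g.weight[best_id], g.weight[v.id]
            if wv > wb or (
                wv == wb and _max_tiebreak(g.by_id[v.id]) < _max_tiebreak(g.by_id[best_id])
            ):
                best_id = v.id
    if best_id is None:
        return None
    path: list[AnchorBlock] = []
    cur: int | None = best_id
    while cur is not None:
        path.append(g.by_id[cur])
        cur = g.parent[cur]
    path.reverse()
    return path


def _max_tiebreak(v: AnchorBlock) -> tuple[str, int, int]:
    return (v.query.chrom, v.query.start, v.id)


def extract_blocks(
    anchors: Sequence[AnchorBlock], resolution: Resolution
) -> list[SyntenyBlock]:
    """Iteratively extract synteny blocks at the given resolution.

    Per component: take the heaviest chain; if its query span (last anchor
    end minus first anchor start) reaches ``min_block_size``, emit it, remove
    its vertices and repeat, else the component is done.  Each vertex ends up
    in at most one block, but emitted blocks may still overlap in genomic
    coordinates when duplications supplied overlapping anchors.

    Returned blocks are sorted by (query chrom, query start, target chrom,
    target start, strand) for deterministic output.
    """
    g = build_dag(anchors, resolution)
    blocks: list[SyntenyBlock] = []
    for key in sorted(g.components):
        while True:
            path = heaviest_path(g, component=key)
            if path is None:
                break
            span = path[-1].query.end - path[0].query.start
            if span < resolution.min_block_size:
                break
            g.remove(a.id for a in path)
            blocks.append(SyntenyBlock.from_anchors(path, resolution))
    blocks.sort(
        key=lambda b: (
            b.query_span.chrom,
            b.query_span.start,
            b.query_span.end,
            b.target_span.chrom,
            b.target_span.start,
            b.strand,
        )
    )
    return blocks
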