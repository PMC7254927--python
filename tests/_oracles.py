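"""Independent brute-force oracles and random-instance generators.

Everything here deliberately avoids the code paths it checks: chain weights
come from exhaustive path enumeration (no dynamic programming), coverage
from per-base bitmaps, simulator truth from a base-level replay of the
rearrangement script, and agreement from per-base label comparison.
"""

from __future__ import annotations

import numpy as np

from synchain.model import (
    AnchorBlock,
    GenomeSide,
    Resolution,
    SyntenyBlock,
    is_syntenic,
)


def random_anchors(
    rng: np.random.Generator,
    n: int,
    n_chroms: int = 2,
    coord_max: int = 2000,
    size_max: int = 100,
) -> list[AnchorBlock]:
    """Random anchors over a couple of chromosome pairs, both strands."""
    anchors = []
    for i in range(n):
        size = int(rng.integers(1, size_max + 1))
        q0 = int(rng.integers(0, coord_max - size))
        t0 = int(rng.integers(0, coord_max - size))
        anchors.append(
            AnchorBlock(
                GenomeSide(f"q{rng.integers(n_chroms)}", q0, q0 + size),
                GenomeSide(f"t{rng.integers(n_chroms)}", t0, t0 + size),
                "+" if rng.integers(2) == 0 else "-",
                id=i,
            )
        )
    return anchors


def adjacency_matrix(
    anchors: list[AnchorBlock], res: Resolution
) -> dict[int, set[int]]:
    """All-pairs O(n^2) evaluation of the syntenic predicate."""
    return {
        a.id: {b.id for b in anchors if b.id != a.id and is_syntenic(a, b, res)}
        for a in anchors
    }


def max_chain_weight(anchors: list[AnchorBlock], res: Resolution) -> int:
    """Maximum summed anchor size over ALL valid chains, by explicit DFS
    enumeration of every path (no memoisation, no topological DP)."""
    adj = adjacency_matrix(anchors, res)
    by_id = {a.id: a for a in anchors}
    best = 0

    def walk(vid: int, weight: int) -> None:
        nonlocal best
        best = max(best, weight)
        for nxt in adj[vid]:
            walk(nxt, weight + by_id[nxt].size)

    for a in anchors:
        walk(a.id, a.size)
    return best


def random_block(
    rng: np.random.Generator,
    q_chrom: str = "chrQ",
    t_chrom: str = "chrT",
    max_anchors: int = 8,
) -> SyntenyBlock:
    """A random valid synteny block (random strand, sizes and gaps)."""
    n = int(rng.integers(1, max_anchors + 1))
    strand = "+" if rng.integers(2) == 0 else "-"
    sizes = rng.integers(1, 200, size=n)
    q_gaps = rng.integers(0, 300, size=n)
    t_gaps = rng.integers(0, 300, size=n)
    q_pos = int(rng.integers(0, 1000))
    t_total = int(sizes.sum() + t_gaps.sum()) + int(rng.integers(0, 500))
    t_pos = t_total if strand == "-" else int(rng.integers(0, 500))
    anchors = []
    for k in range(n):
        size = int(sizes[k])
        q_pos += int(q_gaps[k])
        if strand == "+":
            t_pos += int(t_gaps[k])
            t_iv = (t_pos, t_pos + size)
            t_pos += size
        else:
            t_pos -= int(t_gaps[k])
            t_iv = (t_pos - size, t_pos)
            t_pos -= size
        anchors.append(
            AnchorBlock(
                GenomeSide(q_chrom, q_pos, q_pos + size),
                GenomeSide(t_chrom, *t_iv),
                strand,
                id=k,
            )
        )
        q_pos += size
    return SyntenyBlock.from_anchors(anchors)


def bitmap_union_length(intervals: list[tuple[int, int]], length: int) -> int:
    """Covered-base count via a per-base bitmap."""
    mask = np.zeros(length, dtype=bool)
    for a, b in intervals:
        mask[a:b] = True
    return int(mask.sum())


def replay_script_per_base(cfg, script) -> list[tuple[str, int, int, str, int, int, str]]:
    """Replay a rearrangement script base-by-base and read off the expected
    block partition: (qChrom, qStart, qEnd, tChrom, tStart, tEnd, strand).

    The target genome is modelled as, per chromosome, a literal list of
    (query chrom, query position, orientation) entries, one per base.
    """
    genomes = {
        f"chr{i + 1}": [(f"chr{i + 1}", p, 1) for p in range(cfg.chrom_length)]
        for i in range(cfg.n_chroms)
    }

    def find_run(chrom: str, q_chrom: str, lo: int, hi: int) -> tuple[int, int]:
        idx = [
            i
            for i, (qc, qp, _) in enumerate(genomes[chrom])
            if qc == q_chrom and lo <= qp < hi
        ]
        assert idx == list(range(idx[0], idx[-1] + 1)), "script ops must be non-nested"
        return idx[0], idx[-1] + 1

    for op in script:
        i0, i1 = find_run(op["chrom"], op["chrom"], op["start"], op["end"])
        if op["kind"] == "inversion":
            seg = [(qc, qp, -s) for qc, qp, s in reversed(genomes[op["chrom"]][i0:i1])]
            genomes[op["chrom"]][i0:i1] = seg
        else:
            seg = genomes[op["chrom"]][i0:i1]
            del genomes[op["chrom"]][i0:i1]
            dest = genomes[op["dest_chrom"]]
            j = next(
                (i for i, (qc, qp, _) in enumerate(dest)
                 if qc == op["dest_chrom"] and qp >= op["dest_pos"]),
                len(dest),
            )
            genomes[op["dest_chrom"]] = dest[:j] + seg + dest[j:]

    blocks = []
    for t_chrom in sorted(genomes):
        bases = genomes[t_chrom]
        i = 0
        while i < len(bases):
            j = i + 1
            qc, qp, s = bases[i]
            while j < len(bases) and bases[j] == (qc, qp + s * (j - i), s):
                j += 1
            q_lo = qp if s == 1 else qp - (j - i) + 1
            blocks.append(
                (qc, q_lo, q_lo + (j - i), t_chrom, i, j, "+" if s == 1 else "-")
            )
            i = j
    return blocks


def per_base_agreement(
    predicted: list[SyntenyBlock],
    truth_rows,
    q_sizes: dict[str, int],
) -> tuple[int, int, int, int]:
    """(matched, total truth, missed, spurious) by per-base label comparison."""
    labels = sorted(
        {(b.target.chrom, b.strand) for b in truth_rows}
        | {(b.target_span.chrom, b.strand) for b in predicted}
    )
    code = {lab: k + 1 for k, lab in enumerate(labels)}
    matched = total = missed = spurious = 0
    for chrom, length in q_sizes.items():
        t_arr = np.zeros(length, dtype=np.int32)
        p_arr = np.zeros(length, dtype=np.int32)
        for b in truth_rows:
            if b.query.chrom == chrom:
                t_arr[b.query.start : b.query.end] = code[(b.target.chrom, b.strand)]
        for b in predicted:
            s = b.query_span
            if s.chrom == chrom:
                p_arr[s.start : s.end] = code[(b.target_span.chrom, b.strand)]
        total += int((t_arr > 0).sum())
        matched += int(((t_arr > 0) & (t_arr == p_arr)).sum())
        missed += int(((t_arr > 0) & (p_arr == 0)).sum())
        spurious += int(((p_arr > 0) & (t_arr != p_arr)).sum())
    return matched, total, missed, spurious
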