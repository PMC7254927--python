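"""Synthetic genome pairs with planted rearrangements, for desk-scale testing.

The simulator works at the coordinate level only: the "query" genome is a
set of chromosomes of fixed length, and the "target" genome is produced by
applying segment inversions (strand flips in place) and translocations
(segment moves to another chromosome) at non-nested breakpoints.  Every
maximal conserved segment then becomes one expected synteny block, and each
segment is tiled with gapless anchors whose lengths and spacings are drawn
around configured means with bounded jitter.  Spurious "noise" anchors with
uniformly random placements and strands can be appended; they are labelled
in the planted truth so evaluation can verify their exclusion.

No nucleotide sequence is synthesised: the chaining algorithm consumes
alignment blocks, not sequence, so coordinate-level simulation exercises it
fully without an aligner dependency.

Rearranged segments are drawn long (megabase scale, see
``segment_length_min``/``segment_length_max``) and breakpoints well
separated, so that at any resolution whose ``max_anchor_distance`` is below
the segment scale no two distinct expected blocks can chain together —
which keeps the expected block partition exact in closed form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence, TextIO

import numpy as np

from .io import SizesTable
from .model import AnchorBlock, GenomeSide, Strand, SyntenyError


class SimulationError(ValueError):
    """Infeasible simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated genome pair.

    Defaults describe a small mammalian-chromosome-like scenario: three
    20 Mb chromosomes, two inversions and one translocation of 2-3 Mb
    segments, ~20 kb anchors every ~5 kb (dense alignment coverage), twenty
    random noise anchors, and +/-500 bp jitter on anchor boundaries.
    """

    n_chroms: int = 3
    chrom_length: int = 20_000_000
    n_inversions: int = 2
    n_translocations: int = 1
    anchor_length: int = 20_000
    anchor_spacing: int = 5_000
    noise_anchors: int = 20
    jitter: int = 500
    seed: int = 0
    segment_length_min: int = 2_000_000
    segment_length_max: int = 3_000_000
    min_separation: int = 2_500_000

    def __post_init__(self) -> None:
        if min(self.n_chroms, self.chrom_length) <= 0:
            raise SimulationError("need at least one chromosome of positive length")
        if min(
            self.n_inversions, self.n_translocations, self.noise_anchors, self.jitter
        ) < 0:
            raise SimulationError("counts and jitter must be non-negative")
        if self.anchor_length <= 0 or self.anchor_spacing <= 0:
            raise SimulationError("anchor length and spacing must be positive")
        if self.jitter >= min(self.anchor_spacing, self.anchor_length):
            raise SimulationError("jitter must be smaller than anchor spacing and length")
        if self.n_translocations > 0 and self.n_chroms < 2:
            raise SimulationError("translocations need at least two chromosomes")
        if not 0 < self.segment_length_min <= self.segment_length_max:
            raise SimulationError("invalid rearranged-segment length range")


@dataclass(frozen=True)
class ExpectedBlock:
    """One maximal conserved segment and its placement in the target genome."""

    id: int
    query: GenomeSide
    target: GenomeSide
    strand: Strand


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a simulation run.

    ``script`` replays the rearrangements (kind + breakpoint coordinates on
    the query); ``expected_blocks`` partition the query genome into maximal
    colinear segments with their target placements; ``breakpoints`` are the
    interior (chrom, position) block boundaries on the query;
    ``anchor_labels`` maps anchor id to expected-block id, or to -1 for
    noise anchors.
    """

    script: tuple[dict, ...]
    expected_blocks: tuple[ExpectedBlock, ...]
    breakpoints: tuple[tuple[str, int], ...]
    anchor_labels: dict[int, int]

    @property
    def noise_ids(self) -> frozenset[int]:
        return frozenset(i for i, lab in self.anchor_labels.items() if lab == -1)


def _chrom_name(i: int) -> str:
    return f"chr{i + 1}"


def _draw_disjoint(
    rng: np.random.Generator,
    cfg: SimConfig,
    reserved: dict[str, list[tuple[int, int]]],
    length: int,
    exclude_chrom: str | None = None,
) -> tuple[str, int]:
    """Draw (chrom, start) for a segment of ``length``, keeping it at least
    ``min_separation`` away from chromosome ends and every reserved interval."""
    chroms = [_chrom_name(i) for i in range(cfg.n_chroms)]
    if exclude_chrom is not None:
        chroms = [c for c in chroms if c != exclude_chrom]
    sep = cfg.min_separation
    for _ in range(2000):
        chrom = chroms[rng.integers(len(chroms))]
        lo, hi = sep, cfg.chrom_length - sep - length
        if hi < lo:
            continue
        start = int(rng.integers(lo, hi + 1))
        iv = (start, start + length)
        if all(
            iv[1] + sep <= r0 or r1 + sep <= iv[0] for r0, r1 in reserved[chrom]
        ):
            reserved[chrom].append(iv)
            return chrom, start
    raise SimulationError(
        "could not place a rearranged segment: chromosomes too short for the "
        "requested number of operations at the configured separation"
    )


@dataclass
class _Segment:
    q_chrom: str
    q_start: int
    q_end: int
    strand: Strand = "+"

    @property
    def length(self) -> int:
        return self.q_end - self.q_start


def _plan_rearrangements(rng: np.random.Generator, cfg: SimConfig) -> list[dict]:
    reserved: dict[str, list[tuple[int, int]]] = {
        _chrom_name(i): [] for i in range(cfg.n_chroms)
    }
    script: list[dict] = []
    for _ in range(cfg.n_inversions):
        length = int(rng.integers(cfg.segment_length_min, cfg.segment_length_max + 1))
        chrom, start = _draw_disjoint(rng, cfg, reserved, length)
        script.append(
            {"kind": "inversion", "chrom": chrom, "start": start, "end": start + length}
        )
    for _ in range(cfg.n_translocations):
        length = int(rng.integers(cfg.segment_length_min, cfg.segment_length_max + 1))
        chrom, start = _draw_disjoint(rng, cfg, reserved, length)
        dest_chrom, dest_pos = _draw_disjoint(
            rng, cfg, reserved, 0, exclude_chrom=chrom
        )
        script.append(
            {
                "kind": "translocation",
                "chrom": chrom,
                "start": start,
                "end": start + length,
                "dest_chrom": dest_chrom,
                "dest_pos": dest_pos,
            }
        )
    return script


def apply_script(cfg: SimConfig, script: Sequence[dict]) -> dict[str, list[_Segment]]:
    """Replay a rearrangement script into per-target-chromosome segment lists.

    Each target chromosome is an ordered list of query segments with
    strands; inverted segments flip strand in place, translocated segments
    are cut out and inserted at their destination position.
    """
    boundaries: dict[str, set[int]] = {
        _chrom_name(i): {0, cfg.chrom_length} for i in range(cfg.n_chroms)
    }
    for op in script:
        boundaries[op["chrom"]].update((op["start"], op["end"]))
        if op["kind"] == "translocation":
            boundaries[op["dest_chrom"]].add(op["dest_pos"])
    layout: dict[str, list[_Segment]] = {}
    moved: list[tuple[dict, _Segment]] = []
    for chrom, cuts in boundaries.items():
        pts = sorted(cuts)
        segs = [_Segment(chrom, a, b) for a, b in zip(pts, pts[1:]) if a < b]
        for op in script:
            if op["chrom"] != chrom:
                continue
            for seg in segs:
                inside = op["start"] <= seg.q_start and seg.q_end <= op["end"]
                if not inside:
                    continue
                if op["kind"] == "inversion":
                    seg.strand = "-"
        kept = []
        for seg in segs:
            out = None
            for op in script:
                if (
                    op["kind"] == "translocation"
                    and op["chrom"] == chrom
                    and op["start"] <= seg.q_start
                    and seg.q_end <= op["end"]
                ):
                    out = op
                    break
            if out is None:
                kept.append(seg)
            else:
                moved.append((out, seg))
        layout[chrom] = kept
    for op, seg in moved:
        dest = layout[op["dest_chrom"]]
        idx = len(dest)
        for i, s in enumerate(dest):
            # compare only against the destination chromosome's own segments:
            # earlier insertions carry coordinates from other chromosomes
            if s.q_chrom == op["dest_chrom"] and s.q_start >= op["dest_pos"]:
                idx = i
                break
        dest.insert(idx, seg)
    return layout


def _expected_blocks(layout: dict[str, list[_Segment]]) -> list[ExpectedBlock]:
    blocks: list[ExpectedBlock] = []
    for t_chrom in sorted(layout):
        offset = 0
        for seg in layout[t_chrom]:
            blocks.append(
                ExpectedBlock(
                    id=len(blocks),
                    query=GenomeSide(seg.q_chrom, seg.q_start, seg.q_end),
                    target=GenomeSide(t_chrom, offset, offset + seg.length),
                    strand=seg.strand,
                )
            )
            offset += seg.length
    return blocks


def _tile_block(
    rng: np.random.Generator, cfg: SimConfig, blk: ExpectedBlock
) -> list[AnchorBlock]:
    """Tile one conserved segment with jittered gapless anchors."""

    def draw(mean: int) -> int:
        if cfg.jitter == 0:
            return mean
        return int(rng.integers(mean - cfg.jitter, mean + cfg.jitter + 1))

    anchors: list[AnchorBlock] = []
    pos = blk.query.start + draw(cfg.anchor_spacing)
    while True:
        length = draw(cfg.anchor_length)
        if pos + length > blk.query.end:
            break
        q = GenomeSide(blk.query.chrom, pos, pos + length)
        if blk.strand == "+":
            t0 = blk.target.start + (pos - blk.query.start)
        else:
            t0 = blk.target.start + (blk.query.end - (pos + length))
        t = GenomeSide(blk.target.chrom, t0, t0 + length)
        anchors.append(AnchorBlock(q, t, blk.strand))
        pos += length + draw(cfg.anchor_spacing)
    if not anchors:
        raise SimulationError(
            f"conserved segment {blk.query} too short to hold one anchor"
        )
    return anchors


def simulate_pair(
    cfg: SimConfig,
) -> tuple[list[AnchorBlock], tuple[SizesTable, SizesTable], PlantedTruth]:
    """Generate anchors, sizes tables and planted truth for one genome pair.

    Deterministic for a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    script = _plan_rearrangements(rng, cfg)
    layout = apply_script(cfg, script)
    blocks = _expected_blocks(layout)

    anchors: list[AnchorBlock] = []
    labels: dict[int, int] = {}
    for blk in blocks:
        for a in _tile_block(rng, cfg, blk):
            anchor = a.with_id(len(anchors))
            anchors.append(anchor)
            labels[anchor.id] = blk.id

    q_sizes = SizesTable()
    for i in range(cfg.n_chroms):
        q_sizes.add(_chrom_name(i), cfg.chrom_length)
    t_sizes = SizesTable()
    for t_chrom in sorted(layout):
        t_len = sum(s.length for s in layout[t_chrom])
        if t_len > 0:
            t_sizes.add(t_chrom, t_len)

    t_names = sorted(t_sizes)
    for _ in range(cfg.noise_anchors):
        length = cfg.anchor_length
        q_chrom = _chrom_name(int(rng.integers(cfg.n_chroms)))
        q0 = int(rng.integers(0, cfg.chrom_length - length + 1))
        t_chrom = t_names[int(rng.integers(len(t_names)))]
        t0 = int(rng.integers(0, t_sizes[t_chrom] - length + 1))
        strand: Strand = "+" if rng.integers(2) == 0 else "-"
        anchor = AnchorBlock(
            GenomeSide(q_chrom, q0, q0 + length),
            GenomeSide(t_chrom, t0, t0 + length),
            strand,
            id=len(anchors),
        )
        anchors.append(anchor)
        labels[anchor.id] = -1

    breakpoints = tuple(
        sorted(
            (c, p)
            for c in q_sizes
            for p in _interior_boundaries(cfg, script, c)
        )
    )
    truth = PlantedTruth(
        script=tuple(script),
        expected_blocks=tuple(blocks),
        breakpoints=breakpoints,
        anchor_labels=labels,
    )
    return anchors, (q_sizes, t_sizes), truth


def _interior_boundaries(cfg: SimConfig, script: Sequence[dict], chrom: str) -> set[int]:
    pts: set[int] = set()
    for op in script:
        if op["chrom"] == chrom:
            pts.update((op["start"], op["end"]))
        if op["kind"] == "translocation" and op["dest_chrom"] == chrom:
            pts.add(op["dest_pos"])
    return {p for p in pts if 0 < p < cfg.chrom_length}


# ---------------------------------------------------------------------------
# truth table / script log serialisation

TRUTH_HEADER = "#block_id\tqChrom\tqStart\tqEnd\ttChrom\ttStart\ttEnd\tstrand"


def write_truth(blocks: Iterable[ExpectedBlock], stream: TextIO) -> None:
    stream.write(TRUTH_HEADER + "\n")
    for b in blocks:
        stream.write(
            f"{b.id}\t{b.query.chrom}\t{b.query.start}\t{b.query.end}\t"
            f"{b.target.chrom}\t{b.target.start}\t{b.target.end}\t{b.strand}\n"
        )


def read_truth(stream: Iterable[str]) -> list[ExpectedBlock]:
    blocks: list[ExpectedBlock] = []
    for raw in stream:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 8:
            raise SyntenyError(f"truth table rows need 8 columns, got {len(f)}")
        blocks.append(
            ExpectedBlock(
                id=int(f[0]),
                query=GenomeSide(f[1], int(f[2]), int(f[3])),
                target=GenomeSide(f[4], int(f[5]), int(f[6])),
                strand=f[7],  # type: ignore[arg-type]
            )
        )
    return blocks


def write_script_log(cfg: SimConfig, truth: PlantedTruth, stream: TextIO) -> None:
    json.dump(
        {
            "config": asdict(cfg),
            "script": list(truth.script),
            "breakpoints": [list(bp) for bp in truth.breakpoints],
            "noise_anchor_ids": sorted(truth.noise_ids),
            "anchor_labels": {str(k): v for k, v in sorted(truth.anchor_labels.items())},
        },
        stream,
        indent=2,
        sort_keys=True,
    )
    stream.write("\n")
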