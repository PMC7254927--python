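"""Core domain types and the pairwise synteny predicate.

A synteny block is a chain of gapless alignment anchors that, in each of the
two genomes being compared, (i) lie on one chromosome, (ii) do not overlap,
(iii) share strand, and (iv) run monotonically along the chromosome —
increasing coordinates on the ``+`` strand, decreasing on ``-``.

Coordinates are 0-based, half-open everywhere inside the library (the PSL
convention); conversions to other conventions happen only at the I/O
boundary.  The query side of every anchor is normalised to the ``+`` strand:
the anchor's ``strand`` flag records the orientation of the target interval
relative to the query, and a ``-`` anchor's target interval is still stored
in forward target coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Literal, Sequence

Strand = Literal["+", "-"]
Side = Literal["query", "target"]


class SyntenyError(ValueError):
    """Invalid domain object or operation."""


class IncomparableAnchorsError(SyntenyError):
    """Raised when a genomic distance is requested across different chromosomes."""


@dataclass(frozen=True, slots=True)
class GenomeSide:
    """A half-open interval [start, end) on one chromosome of one genome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise SyntenyError(
                f"interval [{self.start}, {self.end}) on {self.chrom!r} is empty "
                f"or has negative coordinates"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeSide") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True, slots=True)
class AnchorBlock:
    """One gapless pairwise alignment block; a vertex of the chaining DAG.

    Gapless means contiguous in both genomes, so the query and target
    intervals have identical length (the anchor *size*, which is also the
    vertex's initial weight in the chaining DP).  Overlapping anchors are
    legal input: duplications are expressed as overlapping alignment blocks.
    """

    query: GenomeSide
    target: GenomeSide
    strand: Strand
    id: int = -1

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise SyntenyError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.query.length != self.target.length:
            raise SyntenyError(
                f"anchor is not gapless: query span {self.query.length} != "
                f"target span {self.target.length}"
            )

    @property
    def size(self) -> int:
        """Aligned length in bases (equal on both sides)."""
        return self.query.length

    def with_id(self, new_id: int) -> "AnchorBlock":
        return AnchorBlock(self.query, self.target, self.strand, new_id)


@dataclass(frozen=True, slots=True)
class Resolution:
    """The (b_min, d_max) pair bounding output granularity.

    ``min_block_size`` (b_min): minimum query-genome span, in bases, a chain
    must reach to be reported as a synteny block.

    ``max_anchor_distance`` (d_max): maximum gap, in bases, tolerated between
    two consecutive anchors of a chain — on *both* genomes.
    """

    min_block_size: int
    max_anchor_distance: int

    def __post_init__(self) -> None:
        if self.min_block_size < 0 or self.max_anchor_distance < 0:
            raise SyntenyError("resolution parameters must be non-negative")


def gap(a: AnchorBlock, b: AnchorBlock, side: Side) -> int:
    """Genomic distance between two anchors on one genome side.

    Returns the number of bases strictly between the two intervals
    (``later.start - earlier.end``); 0 for abutting intervals and a negative
    value when they overlap, so a single comparison answers both "how far
    apart" and "do they overlap".

    Raises
    ------
    IncomparableAnchorsError
        If the two anchors sit on different chromosomes on ``side``.
    """
    ia = a.query if side == "query" else a.target
    ib = b.query if side == "query" else b.target
    if ia.chrom != ib.chrom:
        raise IncomparableAnchorsError(
            f"anchors on different {side} chromosomes: {ia.chrom!r} vs {ib.chrom!r}"
        )
    if ia.start <= ib.start:
        return ib.start - ia.end
    return ia.start - ib.end


def is_syntenic(a: AnchorBlock, b: AnchorBlock, res: Resolution) -> bool:
    """Whether ``b`` can directly follow ``a`` in a synteny chain (edge a -> b).

    True iff the two anchors share query chromosome, target chromosome and
    strand; ``b`` follows ``a`` on the query without overlap; on the target,
    ``b`` follows ``a`` for ``+`` anchors and precedes it for ``-`` anchors
    (again without overlap); and both the query gap and the target gap are at
    most ``res.max_anchor_distance``.  The relation is deliberately
    asymmetric and irreflexive — that is what makes the chaining graph
    acyclic.  Incomparable anchors simply yield False.
    """
    if (
        a.query.chrom != b.query.chrom
        or a.target.chrom != b.target.chrom
        or a.strand != b.strand
    ):
        return False
    qgap = b.query.start - a.query.end
    if qgap < 0 or qgap > res.max_anchor_distance:
        return False
    if a.strand == "+":
        tgap = b.target.start - a.target.end
    else:
        tgap = a.target.start - b.target.end
    return 0 <= tgap <= res.max_anchor_distance


@dataclass(frozen=True, slots=True)
class SyntenyBlock:
    """An extracted chain of anchors plus its derived spans and weight.

    Construct through :meth:`from_anchors`, which checks the synteny
    properties; the raw constructor performs no validation.
    """

    anchors: tuple[AnchorBlock, ...]
    strand: Strand
    query_span: GenomeSide
    target_span: GenomeSide
    weight: int

    @classmethod
    def from_anchors(
        cls,
        anchors: Sequence[AnchorBlock],
        resolution: Resolution | None = None,
    ) -> "SyntenyBlock":
        """Build a block from anchors in query order, validating invariants.

        Checks: shared chromosomes and strand; pairwise-disjoint, strictly
        increasing query intervals; pairwise-disjoint target intervals,
        increasing for ``+`` and decreasing for ``-``; and, when a
        ``resolution`` is given, every consecutive gap on both sides within
        ``max_anchor_distance``.
        """
        if not anchors:
            raise SyntenyError("a synteny block needs at least one anchor")
        first = anchors[0]
        for x in anchors[1:]:
            if (
                x.query.chrom != first.query.chrom
                or x.target.chrom != first.target.chrom
                or x.strand != first.strand
            ):
                raise SyntenyError("anchors of one block must share chromosomes and strand")
        for prev, cur in zip(anchors, anchors[1:]):
            qg = gap(prev, cur, "query")
            if cur.query.start < prev.query.end or qg < 0:
                raise SyntenyError("query intervals must be disjoint and increasing")
            if first.strand == "+":
                tg = cur.target.start - prev.target.end
            else:
                tg = prev.target.start - cur.target.end
            if tg < 0:
                raise SyntenyError(
                    "target intervals must be disjoint and monotone for the strand"
                )
            if resolution is not None:
                if qg > resolution.max_anchor_distance or tg > resolution.max_anchor_distance:
                    raise SyntenyError(
                        f"consecutive anchor gap exceeds max_anchor_distance="
                        f"{resolution.max_anchor_distance}"
                    )
        qs = GenomeSide(
            first.query.chrom,
            min(a.query.start for a in anchors),
            max(a.query.end for a in anchors),
        )
        ts = GenomeSide(
            first.target.chrom,
            min(a.target.start for a in anchors),
            max(a.target.end for a in anchors),
        )
        return cls(
            anchors=tuple(anchors),
            strand=first.strand,
            query_span=qs,
            target_span=ts,
            weight=sum(a.size for a in anchors),
        )

    def __len__(self) -> int:
        return len(self.anchors)

    def __iter__(self) -> Iterator[AnchorBlock]:
        return iter(self.anchors)

    @property
    def anchor_ids(self) -> tuple[int, ...]:
        return tuple(a.id for a in self.anchors)
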