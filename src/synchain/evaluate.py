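"""Coverage and truth-agreement statistics for emitted synteny blocks.

Coverage answers "how much of each genome do the blocks span", with
overlapping spans counted once — the same quantity a whole-genome synteny
run reports as percent genome coverage.  Agreement scores predicted blocks
against a simulator's planted truth base-by-base on the query genome: a
query base is credited only when a predicted block covering it places it on
the truth's target chromosome and strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, TextIO

from intervaltree import Interval, IntervalTree

from .io import SizesTable
from .model import GenomeSide, Side, SyntenyBlock, SyntenyError
from .simulate import ExpectedBlock, PlantedTruth


def _merged(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Disjoint, sorted union of half-open intervals."""
    nonempty = [(a, b) for a, b in intervals if a < b]
    if not nonempty:
        return []
    tree = IntervalTree(Interval(a, b) for a, b in nonempty)
    tree.merge_overlaps(strict=False)  # also merge abutting intervals
    return sorted((iv.begin, iv.end) for iv in tree)


def _total(merged: Sequence[tuple[int, int]]) -> int:
    return sum(b - a for a, b in merged)


def _overlap_len(
    xs: Sequence[tuple[int, int]], ys: Sequence[tuple[int, int]]
) -> int:
    """Total overlap between two disjoint sorted interval lists (two-pointer)."""
    i = j = out = 0
    while i < len(xs) and j < len(ys):
        a0, a1 = xs[i]
        b0, b1 = ys[j]
        out += max(0, min(a1, b1) - max(a0, b0))
        if a1 <= b1:
            i += 1
        else:
            j += 1
    return out


@dataclass(frozen=True)
class CoverageReport:
    """Per-chromosome and genome-wide covered fractions for one genome side."""

    per_chrom: Mapping[str, tuple[int, float]]  # chrom -> (covered bases, fraction)
    covered_bases: int
    total_bases: int

    @property
    def genome_fraction(self) -> float:
        return self.covered_bases / self.total_bases if self.total_bases else 0.0

    def to_tsv(self) -> str:
        lines = ["#chrom\tcovered\tfraction"]
        for chrom in sorted(self.per_chrom):
            covered, frac = self.per_chrom[chrom]
            lines.append(f"{chrom}\t{covered}\t{frac:.6f}")
        lines.append(
            f"#genome\t{self.covered_bases}\t{self.genome_fraction:.6f}"
        )
        return "\n".join(lines) + "\n"

    def summary(self) -> str:
        return (
            f"covered {self.covered_bases:,} of {self.total_bases:,} bases "
            f"({100 * self.genome_fraction:.2f}%)"
        )


def coverage(
    blocks: Sequence[SyntenyBlock], sizes: SizesTable, side: Side = "query"
) -> CoverageReport:
    """Fraction of one genome covered by block spans (union, overlaps once)."""
    spans: dict[str, list[tuple[int, int]]] = {}
    for blk in blocks:
        span = blk.query_span if side == "query" else blk.target_span
        if span.chrom not in sizes:
            raise SyntenyError(
                f"{side} chromosome {span.chrom!r} missing from sizes table"
            )
        spans.setdefault(span.chrom, []).append((span.start, span.end))
    per_chrom: dict[str, tuple[int, float]] = {}
    covered_total = 0
    for chrom, length in sizes.items():
        covered = _total(_merged(spans.get(chrom, [])))
        per_chrom[chrom] = (covered, covered / length)
        covered_total += covered
    return CoverageReport(
        per_chrom=per_chrom,
        covered_bases=covered_total,
        total_bases=sum(sizes.values()),
    )


Label = tuple[str, str]  # (target chrom, strand)


@dataclass(frozen=True)
class AgreementReport:
    """Base-wise agreement between predicted blocks and planted truth.

    matched_fraction — query bases whose predicted target chromosome and
    strand match the truth, over all truth bases; split_count — number of
    predicted blocks in excess of truth blocks (0 when the partition was
    recovered block-for-block); missed_bases — truth bases no predicted
    block covers; spurious_bases — predicted bases that disagree with (or
    fall outside) the truth labelling.
    """

    matched_fraction: float
    split_count: int
    missed_bases: int
    spurious_bases: int

    def as_dict(self) -> dict[str, float | int]:
        return {
            "matched_fraction": self.matched_fraction,
            "split_count": self.split_count,
            "missed_bases": self.missed_bases,
            "spurious_bases": self.spurious_bases,
        }

    def summary(self) -> str:
        return (
            f"matched fraction {self.matched_fraction:.4f}, "
            f"splits {self.split_count}, missed {self.missed_bases:,} bases, "
            f"spurious {self.spurious_bases:,} bases"
        )


def _labelled_spans(
    rows: Sequence[tuple[GenomeSide, Label]]
) -> dict[tuple[str, Label], list[tuple[int, int]]]:
    out: dict[tuple[str, Label], list[tuple[int, int]]] = {}
    for span, label in rows:
        out.setdefault((span.chrom, label), []).append((span.start, span.end))
    return {k: _merged(v) for k, v in out.items()}


def agreement(
    predicted: Sequence[SyntenyBlock],
    truth: PlantedTruth | Sequence[ExpectedBlock],
) -> AgreementReport:
    """Score predicted blocks against planted truth, base-wise on the query."""
    rows: Sequence[ExpectedBlock]
    rows = truth.expected_blocks if isinstance(truth, PlantedTruth) else truth

    truth_spans = _labelled_spans(
        [(b.query, (b.target.chrom, b.strand)) for b in rows]
    )
    pred_spans = _labelled_spans(
        [(b.query_span, (b.target_span.chrom, b.strand)) for b in predicted]
    )
    truth_by_chrom: dict[str, list[tuple[int, int]]] = {}
    pred_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for (chrom, _), ivs in truth_spans.items():
        truth_by_chrom.setdefault(chrom, []).extend(ivs)
    for (chrom, _), ivs in pred_spans.items():
        pred_by_chrom.setdefault(chrom, []).extend(ivs)
    truth_by_chrom = {c: _merged(v) for c, v in truth_by_chrom.items()}
    pred_by_chrom = {c: _merged(v) for c, v in pred_by_chrom.items()}

    total_truth = sum(_total(v) for v in truth_by_chrom.values())
    matched = sum(
        _overlap_len(ivs, pred_spans.get(key, []))
        for key, ivs in truth_spans.items()
    )
    missed = total_truth - sum(
        _overlap_len(ivs, pred_by_chrom.get(chrom, []))
        for chrom, ivs in truth_by_chrom.items()
    )
    spurious = sum(
        _total(ivs) - _overlap_len(ivs, truth_spans.get(key, []))
        for key, ivs in pred_spans.items()
    )
    return AgreementReport(
        matched_fraction=matched / total_truth if total_truth else 1.0,
        split_count=max(0, len(predicted) - len(rows)),
        missed_bases=missed,
        spurious_bases=spurious,
    )
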