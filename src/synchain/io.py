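"""Reading and writing anchors and synteny blocks: PSL, PAF, sizes tables.

PSL is UCSC's 21-column tab-separated pairwise alignment format.  Per PSL
convention, the per-block target starts of a ``-`` strand record are given in
reverse-strand coordinates; on read they are converted to forward-strand
half-open intervals (``tSize - revStart - blockSize`` .. ``tSize - revStart``)
and the inverse conversion is applied on write.  Gapped records (blockCount >
1, or a PAF CIGAR containing indels) are decomposed into gapless
:class:`~synchain.model.AnchorBlock` pieces on read, since the chaining
algorithm is defined on gapless blocks.

Output is headerless PSL; the reader tolerates and skips the optional
5-line ``psLayout`` header.
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence, TextIO

from .model import AnchorBlock, GenomeSide, Strand, SyntenyBlock, SyntenyError

PSL_COLUMNS = 21

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


class ParseError(ValueError):
    """Malformed input line; message carries the 1-based line number."""

    def __init__(self, line_no: int, message: str):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


class SizesTable(dict):
    """Chromosome name -> length (bases) for one genome side.

    Lengths must be positive; re-adding a name with a different length is an
    error (names are unique per genome).
    """

    def add(self, name: str, length: int) -> None:
        if length <= 0:
            raise SyntenyError(f"chromosome {name!r} has non-positive length {length}")
        if name in self and self[name] != length:
            raise SyntenyError(
                f"conflicting lengths for chromosome {name!r}: "
                f"{self[name]} vs {length}"
            )
        self[name] = length


def read_sizes(stream: Iterable[str]) -> SizesTable:
    """Read a two-column ``name<TAB>length`` chromosome sizes file."""
    table = SizesTable()
    for i, raw in enumerate(stream, 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ParseError(i, f"expected 2 columns in sizes file, got {len(parts)}")
        try:
            table.add(parts[0], int(parts[1]))
        except ValueError as exc:
            raise ParseError(i, str(exc)) from None
    return table


def write_sizes(table: SizesTable, stream: TextIO) -> None:
    for name in sorted(table):
        stream.write(f"{name}\t{table[name]}\n")


def _split_int_list(field: str, line_no: int, what: str) -> list[int]:
    items = [x for x in field.split(",") if x != ""]
    try:
        return [int(x) for x in items]
    except ValueError:
        raise ParseError(line_no, f"non-numeric entry in {what}: {field!r}") from None


def read_psl(stream: Iterable[str]) -> tuple[list[AnchorBlock], SizesTable, SizesTable]:
    """Parse PSL lines into gapless anchors plus query/target sizes tables.

    Each record is expanded into one anchor per entry of
    ``blockCount``/``blockSizes``/``qStarts``/``tStarts``.  Anchor ids are
    assigned in file order, then block order within a record.
    """
    anchors: list[AnchorBlock] = []
    q_sizes = SizesTable()
    t_sizes = SizesTable()
    in_header = False
    header_seen = 0
    for line_no, raw in enumerate(stream, 1):
        line = raw.rstrip("\n")
        if line_no == 1 and line.startswith("psLayout"):
            in_header = True
        if in_header:
            header_seen += 1
            if line.startswith("---") or header_seen >= 5:
                in_header = False
            continue
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != PSL_COLUMNS:
            raise ParseError(
                line_no, f"expected {PSL_COLUMNS} tab-separated columns, got {len(fields)}"
            )
        try:
            strand = fields[8]
            q_name = fields[9]
            q_size = int(fields[10])
            q_start, q_end = int(fields[11]), int(fields[12])
            t_name = fields[13]
            t_size = int(fields[14])
            t_start, t_end = int(fields[15]), int(fields[16])
            block_count = int(fields[17])
        except ValueError:
            raise ParseError(line_no, "non-numeric coordinate field") from None
        if strand not in ("+", "-"):
            raise ParseError(line_no, f"unsupported strand {strand!r}")
        block_sizes = _split_int_list(fields[18], line_no, "blockSizes")
        q_starts = _split_int_list(fields[19], line_no, "qStarts")
        t_starts = _split_int_list(fields[20], line_no, "tStarts")
        if not (len(block_sizes) == len(q_starts) == len(t_starts) == block_count):
            raise ParseError(
                line_no,
                f"blockCount={block_count} disagrees with list lengths "
                f"{len(block_sizes)}/{len(q_starts)}/{len(t_starts)}",
            )
        if q_end > q_size or t_end > t_size:
            raise ParseError(line_no, "record end beyond declared sequence size")
        try:
            q_sizes.add(q_name, q_size)
            t_sizes.add(t_name, t_size)
        except SyntenyError as exc:
            raise ParseError(line_no, str(exc)) from None
        for size, qs, ts in zip(block_sizes, q_starts, t_starts):
            if qs + size > q_size:
                raise ParseError(line_no, "query block exceeds declared qSize")
            if strand == "+":
                t_iv = (ts, ts + size)
            else:
                # reverse-strand block start -> forward half-open interval
                t_iv = (t_size - ts - size, t_size - ts)
            if ts + size > t_size or t_iv[0] < 0:
                raise ParseError(line_no, "target block exceeds declared tSize")
            try:
                anchors.append(
                    AnchorBlock(
                        GenomeSide(q_name, qs, qs + size),
                        GenomeSide(t_name, *t_iv),
                        strand,  # type: ignore[arg-type]
                        id=len(anchors),
                    )
                )
            except SyntenyError as exc:
                raise ParseError(line_no, str(exc)) from None
    return anchors, q_sizes, t_sizes


def _parse_cigar(cigar: str, line_no: int) -> list[tuple[int, str]]:
    ops = []
    pos = 0
    for m in _CIGAR_RE.finditer(cigar):
        if m.start() != pos:
            raise ParseError(line_no, f"malformed CIGAR {cigar!r}")
        ops.append((int(m.group(1)), m.group(2)))
        pos = m.end()
    if pos != len(cigar) or not ops:
        raise ParseError(line_no, f"malformed CIGAR {cigar!r}")
    return ops


def read_paf(stream: Iterable[str]) -> tuple[list[AnchorBlock], SizesTable, SizesTable]:
    """Parse PAF lines (12 mandatory columns, optional ``cg:Z:`` CIGAR tag).

    With a CIGAR the record is split into one gapless anchor per M/=/X run;
    insertions and deletions only move the coordinate cursors.  Without a
    CIGAR the record must already be gapless (equal query and target spans).
    For ``-`` strand records the target cursor walks the forward-strand
    target coordinates downwards from ``tEnd``, so anchors come out with
    decreasing target intervals along the query — the orientation a ``-``
    chain requires.
    """
    anchors: list[AnchorBlock] = []
    q_sizes = SizesTable()
    t_sizes = SizesTable()
    for line_no, raw in enumerate(stream, 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise ParseError(line_no, f"expected >= 12 PAF columns, got {len(fields)}")
        try:
            q_name, q_len = fields[0], int(fields[1])
            q_start, q_end = int(fields[2]), int(fields[3])
            strand = fields[4]
            t_name, t_len = fields[5], int(fields[6])
            t_start, t_end = int(fields[7]), int(fields[8])
        except ValueError:
            raise ParseError(line_no, "non-numeric coordinate field") from None
        if strand not in ("+", "-"):
            raise ParseError(line_no, f"unsupported strand {strand!r}")
        if q_end > q_len or t_end > t_len or q_start >= q_end or t_start >= t_end:
            raise ParseError(line_no, "inconsistent PAF coordinates")
        try:
            q_sizes.add(q_name, q_len)
            t_sizes.add(t_name, t_len)
        except SyntenyError as exc:
            raise ParseError(line_no, str(exc)) from None
        cigar = None
        for tag in fields[12:]:
            if tag.startswith("cg:Z:"):
                cigar = tag[5:]
                break
        if cigar is None:
            if q_end - q_start != t_end - t_start:
                raise ParseError(
                    line_no,
                    "record without cg:Z: CIGAR has unequal query/target spans "
                    "and cannot be decomposed into gapless blocks",
                )
            anchors.append(
                AnchorBlock(
                    GenomeSide(q_name, q_start, q_end),
                    GenomeSide(t_name, t_start, t_end),
                    strand,  # type: ignore[arg-type]
                    id=len(anchors),
                )
            )
            continue
        qp = q_start
        tp = t_start if strand == "+" else t_end
        for length, op in _parse_cigar(cigar, line_no):
            if op in ("M", "=", "X"):
                if strand == "+":
                    t_iv = (tp, tp + length)
                    tp += length
                else:
                    t_iv = (tp - length, tp)
                    tp -= length
                anchors.append(
                    AnchorBlock(
                        GenomeSide(q_name, qp, qp + length),
                        GenomeSide(t_name, *t_iv),
                        strand,  # type: ignore[arg-type]
                        id=len(anchors),
                    )
                )
                qp += length
            elif op == "I":
                qp += length
            elif op in ("D", "N"):
                tp += length if strand == "+" else -length
            else:
                raise ParseError(line_no, f"unsupported CIGAR op {op!r} in PAF cg tag")
        t_ok = tp == (t_end if strand == "+" else t_start)
        if qp != q_end or not t_ok:
            raise ParseError(line_no, "CIGAR walk does not reach the record end coordinates")
    return anchors, q_sizes, t_sizes


def read_anchors(
    stream: Iterable[str], fmt: str = "psl", swap: bool = False
) -> tuple[list[AnchorBlock], SizesTable, SizesTable]:
    """Read anchors in either supported format, optionally swapping sides."""
    if fmt == "psl":
        anchors, q_sizes, t_sizes = read_psl(stream)
    elif fmt == "paf":
        anchors, q_sizes, t_sizes = read_paf(stream)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'psl' or 'paf'")
    if swap:
        anchors = [
            AnchorBlock(a.target, a.query, a.strand, a.id) for a in anchors
        ]
        q_sizes, t_sizes = t_sizes, q_sizes
    return anchors, q_sizes, t_sizes


def write_psl(
    blocks: Sequence[SyntenyBlock],
    q_sizes: SizesTable,
    t_sizes: SizesTable,
    stream: TextIO,
) -> int:
    """Write one 21-column PSL record per synteny block; return the line count.

    matches = summed anchor sizes; misMatches/repMatches/nCount = 0 (anchor
    internal identity is unknown at synteny level); the insert columns count
    and sum the positive inter-anchor gaps on each side.  Records are sorted
    by (qName, qStart) so runs are reproducible byte-for-byte.
    """
    records = []
    for blk in blocks:
        q_chrom = blk.query_span.chrom
        t_chrom = blk.target_span.chrom
        if q_chrom not in q_sizes:
            raise SyntenyError(f"query chromosome {q_chrom!r} missing from sizes table")
        if t_chrom not in t_sizes:
            raise SyntenyError(f"target chromosome {t_chrom!r} missing from sizes table")
        t_size = t_sizes[t_chrom]
        q_inserts = [
            b.query.start - a.query.end for a, b in zip(blk.anchors, blk.anchors[1:])
        ]
        if blk.strand == "+":
            t_inserts = [
                b.target.start - a.target.end
                for a, b in zip(blk.anchors, blk.anchors[1:])
            ]
            t_starts = [a.target.start for a in blk.anchors]
        else:
            t_inserts = [
                a.target.start - b.target.end
                for a, b in zip(blk.anchors, blk.anchors[1:])
            ]
            # forward interval -> reverse-strand block start
            t_starts = [t_size - a.target.end for a in blk.anchors]
        row = (
            blk.weight,  # matches
            0, 0, 0,  # misMatches repMatches nCount
            sum(1 for g in q_inserts if g > 0), sum(g for g in q_inserts if g > 0),
            sum(1 for g in t_inserts if g > 0), sum(g for g in t_inserts if g > 0),
            blk.strand,
            q_chrom, q_sizes[q_chrom], blk.query_span.start, blk.query_span.end,
            t_chrom, t_size, blk.target_span.start, blk.target_span.end,
            len(blk.anchors),
            ",".join(str(a.size) for a in blk.anchors) + ",",
            ",".join(str(a.query.start) for a in blk.anchors) + ",",
            ",".join(str(s) for s in t_starts) + ",",
        )
        records.append(row)
    records.sort(key=lambda r: (r[9], r[11], r[13], r[15], r[8]))
    for row in records:
        stream.write("\t".join(str(x) for x in row) + "\n")
    return len(records)
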