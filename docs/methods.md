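# Methods

## Model

`synchain` treats synteny construction as iterated heaviest-path extraction
on a DAG of alignment anchors. An anchor is a gapless pairwise alignment
block: a query interval, a target interval of equal length, and a strand.
The query side is normalised to `+`; the strand flag records target
orientation, and `-` anchors keep their target interval in forward target
coordinates. All coordinates are 0-based, half-open (the PSL convention);
conversions happen only at the I/O boundary.

Anchor `b` is *syntenic to* anchor `a` (edge `a -> b`) when all hold:

- same query chromosome, same target chromosome, same strand;
- `b` follows `a` on the query without overlap (`gap >= 0`);
- on the target, `b` follows `a` for `+` anchors and precedes it for `-`
  anchors, without overlap;
- the gap on the query **and** the gap on the target are both at most
  `d_max`.

The gap is the outer distance between interval boundaries
(`later.start - earlier.end`): negative exactly when the intervals overlap,
so one subtraction decides both the overlap and the distance clause. The
both-sides reading of the distance bound is deliberate: an oversized gap on
either genome is a synteny disruption, and a one-sided reading would chain
across arbitrarily distant loci. Abutting anchors (gap 0) are chainable;
overlapping anchors never are. The predicate is irreflexive and
antisymmetric (every edge strictly advances the query start), so the graph
is acyclic and sorting by query start is a topological order.

## Extraction procedure

Edges only connect anchors with equal (query chromosome, target chromosome,
strand), so the graph splits into independent components. Per component the
loop is: reset every vertex weight to its anchor size and clear parents;
relax edges in topological order (`w(b) <- w(a) + size(b)` on strict
improvement, parent stored); backtrack from the maximum-weight vertex; if
the chain's query span reaches `b_min`, emit it, deactivate its vertices
and repeat, else finish the component. Consequences of this design:

- **DP state is recomputed each round.** Removing the extracted vertices
  invalidates accumulated weights; recomputation is the only way "the
  vertex with maximal weight" stays well-defined, and components keep it
  cheap.
- **Stopping is per-component.** Components are independent subgraphs; a
  short best path in one says nothing about another.
- **The span test uses the query genome.** For gapless anchors both sides
  carry identical aligned length; the query span is the reproducible
  choice.
- **Determinism.** Equal-weight candidates never replace (strict `>`), and
  the maximum vertex tie-breaks by smallest (query chromosome, query start,
  id). Output records are sorted by (qName, qStart). Identical inputs give
  byte-identical outputs; shuffling input order does not change the result.
- **No gap penalty.** The weight of a chain is its total aligned bases;
  gaps cost nothing up to the hard `d_max` cutoff. A consequence worth
  knowing: any anchor that is genuinely syntenic to a chain end — even a
  spurious alignment that lands within `d_max` in consistent order on both
  genomes — increases the chain weight and will be absorbed.

Successors are generated lazily by bisecting the component's
sorted-by-query-start list to the window
`[v.query.end, v.query.end + d_max]` — exact for the query-gap clause — and
filtering by the full predicate, so dense inputs never materialise O(n²)
edges.

## Parameters

- `--minBlockSize` (`b_min`), default 1,000,000 bases: minimum query span
  of a reported block. 1 Mb is the scale commonly used for interspecies
  chromosome-level comparisons; drop it to ~100 kb for fragmented
  assemblies.
- `--maxAnchorDistance` (`d_max`), default 1,000,000 bases: maximum
  per-genome gap between chained anchors. Raising it merges across larger
  unaligned stretches; lowering it splits blocks at smaller disruptions.

Both flags accept single- and double-dash spellings.

## File formats

PSL (21 columns) is read and written; PAF (12 columns + `cg:Z:`) is read.
Gapped records are decomposed into gapless anchors: per PSL block list
entry, or per M/=/X CIGAR run (I/D only move the cursors). For `-` strand
PSL records the per-block target starts are reverse-strand coordinates and
are converted to forward intervals on read (`tSize - revStart - size`);
for `-` strand PAF CIGARs the target cursor walks downward from `tEnd`. In
written records, `matches` is the summed anchor size, the insert columns
count/sum the positive inter-anchor gaps per side, and
`misMatches`/`repMatches`/`nCount` are zero — anchor-internal identity is
unknown at synteny level. A PAF record without a CIGAR is accepted only if
already gapless (equal spans).

## Simulator

The simulator emulates a pair of genomes related by large-scale
rearrangements, at the coordinate level only — the chaining algorithm
consumes alignment blocks, not sequence, so synthesising nucleotides would
add an aligner dependency without adding test power. The query genome is
`n_chroms` chromosomes of `chrom_length` (default 3 × 20 Mb); the target is
derived by applying `n_inversions` strand flips and `n_translocations`
inter-chromosomal moves (defaults 2 and 1) to segments of 2–3 Mb drawn at
non-nested breakpoints at least 2.5 Mb apart (`segment_length_min/max`,
`min_separation`). Non-nested, well-separated breakpoints keep the expected
block partition computable in closed form, and the megabase segment scale
guarantees that at any resolution with `d_max` below ~2 Mb no two distinct
expected blocks can chain across a breakpoint. Every conserved segment is
tiled with anchors of ~20 kb every ~5 kb, with boundaries jittered by up to
±500 bp (`anchor_length`, `anchor_spacing`, `jitter`) — dense coverage of
the kind a whole-genome aligner produces for close species. `noise_anchors`
(default 20) spurious anchors with uniform random placement and strand are
appended and labelled in the truth.

What the simulation does **not** model: sequence divergence and alignment
error, micro-rearrangements inside blocks, tandem duplications and nested
rearrangements, assembly fragmentation. Passing the recovery tests
therefore demonstrates the chaining logic (order/orientation/distance
handling, component separation, filtering) on clean anchor sets, not
robustness to alignment artefacts. One consequence of uniform noise
placement is worth stating: with probability on the order of a few percent
per run, a noise anchor lands genuinely syntenic to a real chain end
(consistent order and strand within `d_max` on both genomes) and is then —
correctly, under the model — chained into the block; such an anchor is
indistinguishable from signal by the synteny definition itself.

## Evaluation

Coverage merges block spans per chromosome into a disjoint union (overlaps
counted once) and divides by chromosome/genome length. Agreement scores
predictions against the planted truth base-wise on the query genome: a base
is *matched* when a predicted block covering it places it on the truth's
target chromosome and strand — the coordinate-exact analogue of comparing
homologous-chromosome label assignments; *missed* bases have no covering
prediction, *spurious* bases are predicted but mislabelled or outside the
truth; `split_count` is the number of predicted blocks in excess of truth
blocks. With overlapping predicted blocks (duplications), a base disagreeing
under two different labels is counted once per label.

## Numerical and degenerate-input choices

- Empty anchor sets, empty components and empty files yield empty outputs,
  not errors; infeasible simulator configurations (segments too short to
  hold one anchor, breakpoints that cannot be placed) raise.
- A fully duplicated anchor pile (all intervals overlapping) has no edges:
  with `b_min = 0` it yields exactly one single-anchor block per anchor.
- A perfectly colinear anchor set with `b_min = 0` and `d_max` at least the
  genome length yields exactly one block containing every anchor.
- Sizes tables reject non-positive and conflicting lengths; writing a block
  whose chromosome is absent from the sizes table is an error.

## Test-scale choices

The optimality suite checks every extraction round of 500 random instances
of up to 12 anchors against exhaustive enumeration of all chains (the
brute-force oracle enumerates paths explicitly, with no dynamic
programming); simulator truth is cross-checked by a literal per-base replay
of the rearrangement script on 4 kb toy chromosomes; recovery runs 20
seeds of the default 60 Mb configuration. These sizes complete in seconds
while covering every code path at full depth.

## Known limitations

- Blocks are reported greedily; the k-th block is conditionally optimal
  given the first k−1, not part of a jointly optimal partition.
- No affine or scored gap penalties, and no trimming of coordinate overlap
  between emitted blocks (both deliberate non-goals).
- `+` and `-` chains are never merged into strand-mixed blocks.
- Binary alignment containers are out of scope; inputs arrive as PSL/PAF
  text.
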