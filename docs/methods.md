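# Methods

This note records the model, the concrete choices made where the design
was open, and what the synthetic benchmarks do and do not demonstrate.

## Input contract

One GTF per cell, exon records grouped by `transcript_id`, each transcript
carrying a numeric confidence in the attribute named by `--score-attr`
(default `cov`). Scores must lie in [0, 1]; if any value falls outside,
per-cell min–max normalization `(x − min)/(max − min)` is applied (a file
with a single distinct out-of-range value maps to 1.0). Single-exon
transcripts are counted and discarded on load: the method extends intron
chains, and a transcript without a junction has no chain to extend.
Coordinates are GTF-style 1-based inclusive; a junction is
`(last base of upstream exon, first base of downstream exon)` and its
intron is the closed interval `[donor+1, acceptor−1]`. Fragments are only
ever compared within identical (chromosome, strand); strand `.` is a
distinct value, so unstranded fragments never merge with stranded ones.

## Fragment graph

One vertex per distinct (chromosome, strand, intron chain), carrying every
(cell, fragment, score) support. Collapsing identical chains is
semantically neutral for path enumeration — any path through per-fragment
duplicates yields the same merged chain — and guarantees acyclicity, since
every edge then strictly extends the chain to the right. An edge u → v
requires suffix<sub>k</sub>(u) = prefix<sub>k</sub>(v) for some k ≥ 1 with
v extending beyond u; the maximal such k is stored. Chains wholly
contained in another receive no edge (merging would add nothing); they
remain vertices and seed their own single-vertex paths. No explicit gene
partitioning is done: weakly connected components serve as loci.

## Merging score and path search

F(p) = BJ(p) · NJ(p). Compatibility of fragment t with path p requires a
shared junction and no *conflicting* junction. Conflict is defined as: a
fragment junction absent from the chain whose intron interval overlaps any
chain intron interval. This is the unambiguous, checkable reading;
junctions lying entirely outside the chain's intron span (e.g. beyond its
ends) do not conflict, so fragments extending past the path still count
toward the junctions they share.

F is not prefix-monotone: appending junctions grows NJ but can shrink BJ,
and compatibility of previously counted fragments can flip as the chain
grows. The DP therefore rescores every extension against the full merged
chain instead of reusing per-prefix junction scores. The caps — top
pn = 15 paths per vertex, top pc = 100 per component — are the efficiency
heuristic; with both disabled the search provably (and, in the tests,
empirically on random components) equals exhaustive enumeration. Because F
depends only on the merged chain, identical chains reached through
different vertex sequences share one score computation via a memo on the
fragment index.

Ties are broken totally everywhere (F desc, junction count desc, chain
lexicographic, vertex sequence), so output is byte-deterministic. The
final candidate set deduplicates chains globally, keeping the max-F
instance. Terminal exon coordinates of a candidate take the extremal
starts/ends over input fragments whose first (last) junction equals the
chain's first (last) junction — fragments' terminal exons may be
incomplete, and extremal coordinates preserve all observed exonic
sequence.

## Features

The schema fills three categories with exactly 30 general and 21
cell-specific features; it is registry-driven (name → accessor), so it can
be revised without touching the extraction code, and the version string
`beaver-features-1` is embedded in model bundles and rejected on mismatch.

General (30): five summary statistics (min, median, mean, max, population
std) over each of {per-junction all-cell scores J(j, p), per-junction
supporting-cell counts, per-junction compatible-fragment counts} (15);
plus NJ, BJ, F, number and proportion of supporting cells, number and
proportion of cells containing the full chain in a single fragment, number
of constituent vertices, single-fragment indicator, longest single
fragment's fraction of the chain, min/mean/max consecutive-vertex overlap,
total compatible support score, and total compatible-fragment count (15).

Cell-specific (21): the same five statistics over the cell's own junction
scores and per-junction fragment counts (10); plus the cell's bottleneck,
compatible-fragment count, total score, fraction and count of the chain's
junctions expressed in the cell, full-chain-in-cell indicator, best single
fragment's score and chain fraction, the cell's library size (total input
fragments), the cell's bottleneck rank among supporting cells, and the
candidate's F (11).

Population standard deviation is used because it is defined for a single
junction (0). A (candidate, cell) pair is eligible when ≥ 1 junction of
the candidate appears in any fragment of the cell — mere presence, no
compatibility requirement; the compatibility-filtered quantities appear as
separate features rather than in the eligibility rule.

## Models, labels, thresholds

Both models are `RandomForestClassifier(n_estimators=100, max_depth=12)`
with a fixed seed recorded in the bundle. General labels: candidate chain
∈ union of all cells' truths (or the reference annotation when per-cell
truth is unavailable, as on real data). Specific labels: chain ∈ that
cell's own truth. Chromosomes 1–9 (with or without `chr` prefixes) train;
everything else is held out; the split is asserted disjoint and
exhaustive. "Below the threshold is filtered out" is implemented as keep
score ≥ θ (boundary kept), θ default 0.2. No class re-weighting is
applied: the general-stage filter is itself the class-balancing mechanism
for the pair-level training set. The final emission threshold τ defaults
to 0.5 and only affects which pairs are written as output GTFs; evaluation
consumes the full scored pair list, so sensitivity sweeps are unaffected
by τ.

## Evaluation

A prediction matches iff its full (chromosome, strand, junction list)
equals a truth chain. Duplicate predictions of one chain credit one match;
all occurrences count in the denominator. Adjusted precision removes one
transcript at a time in increasing score order (ties by chain) and stops
at the first point where the match count equals the target — the finest
realization of a score sweep, equal to a point on the precision–recall
curve. It is computed per cell. Cells with empty predictions report NA
precision rather than 0.

## Synthetic data

The generator plants genes whose isoforms are subsets of shared exon
slots (all isoforms keep the first two slots, so isoforms of a gene share
their first junction and land in one component). Per (isoform, cell):
expressed with probability `expression_prob` (0.5 at the tiny/small
scales; 0.35 at the medium scale so the medium fixture has realistic
sparsity); expressed chains are cut into contiguous junction windows
overlapping consecutively by ≥ 1 junction; individual fragments drop out
with `dropout_prob` (0.1); scores are
`clamp(0.4·truth + U(0, 0.55), 0, 1)`; with probability `decoy_rate`
(0.05) a non-expressed isoform emits a decoy whose one shifted acceptor
creates a junction conflicting with the true chain.

Fragmentation cut positions and overlap lengths are *canonical per
isoform*: drawn once, then sampled per cell. This emulates coverage gaps
that recur at the same weakly covered stretches of a transcript across
cells, and it is also what keeps the distinct-window vocabulary per locus
small enough that the planted chain is recoverable under the default
pc = 100 component cap — with fully independent per-cell cut points the
per-component path count explodes combinatorially and true chains can
rank below the cap. Genes alternate between chromosomes 1–9 and 10–18 so
the train/test split is always exercised. Fixture scales: tiny 3 genes ×
3 cells (unit tests), small 50 × 10 (integration), medium 300 × 30
(end-to-end evaluation; ~17 000 input fragments, chosen to exercise
thousand-vertex graphs while a full train/score/evaluate run stays in the
tens of seconds).

What the generator does *not* model: coverage-dependent fragmentation,
correlated dropout across transcripts, PCR artifacts, unannotated
transcription, soft intron boundaries, single-exon transcripts, realistic
expression magnitudes, read-level noise. Passing benchmarks therefore
show that the machinery recovers planted structure and that per-cell
scoring separates truth-correlated from decoy signal under idealized
noise — not performance on real libraries.

## Numerical and degenerate-input choices

Scores are plain float64 sums; the DP-versus-rescore consistency tolerance
is 1e-9. Empty inputs yield empty graphs and empty candidate sets rather
than errors. Training refuses a single-class training set loudly rather
than degrading. A component's isolated vertex still emits its chain as a
single-vertex candidate. Overlapping exons within one input transcript are
a hard parse error; exact duplicate exon records are merged. Cells absent
from truth tables are labeled 0 with a warning. All randomness flows from
a single seed (simulation) and the model seed (forests); reruns are
byte-identical.

## Known limitations

The pn/pc caps make the search heuristic; a true chain can in principle be
displaced by higher-scoring sub-chains or cross-isoform merges in very
dense loci. Compatibility checks interval overlap only — ordering
violations between non-overlapping junctions are not treated as conflicts.
The feature schema is category-faithful but its exact per-feature list is
this package's own; swapping in an alternative registry is supported but
untested. Real-data mode labels both models against a reference
annotation, which overestimates cell-specific accuracy exactly as any
reference-based evaluation does.
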