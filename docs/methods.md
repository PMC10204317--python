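# Methods

## Graph model and coordinates

The in-memory graph holds blunt-ended GFA1 segments, links and named
paths. All coordinates are 0-based, half-open (BED convention); rGFA `SO`
offsets are treated as 0-based, matching minigraph. Sequences are
uppercased at parse time — soft-masking carries no information the
toolkit uses, and discarding case keeps round-trip identity well defined.
W-lines are converted to P-lines (named `sample#hap#seqName`) on input so
there is a single internal walk representation; only P-lines are written.
Link overlaps other than `0M`/`*` are rejected rather than trimmed: all
graph builders this toolkit targets emit blunt-ended graphs, and a
non-blunt link indicates the wrong kind of input.

The position index stores cumulative step offsets per path, giving
O(log n) coordinate→(step, offset) lookups and O(1) amortized
segment→occurrence queries. Round-trip identity
(coordinate → step/offset → coordinate) is a tested invariant.

## Path reconstruction from bubble calls

SV-level graphs carry assembly information only at bubbles, so each
assembly's full walk is rebuilt by following the rank-0 reference
backbone and substituting, inside every called bubble, the assembly's
traversal for the reference interior. Design choices:

* **MISSING calls break the path** into fragments instead of routing
  through the reference allele. Routing would fabricate sequence the
  assembly may not contain; breaking is conservative and keeps downstream
  consumers honest about what is known.
* The backbone is validated to tile contiguously by `SO` offset; the
  first gap or overlap is reported with its size.
* Bubbles whose source/sink are inverted relative to the backbone are
  rejected with a topology error rather than guessed at.
* Congruence counts segment identity only (does the assembly's walk visit
  the nodes that assembly contributed?), not traversal multiplicity.

The call-record dialect is a 6-column TSV
(`chrom start end source sink traversal`, `>s1>s4`-style walks, `.` for
MISSING, empty for a deletion allele); no standard format exists for
curated bubble calls, so the toolkit defines and documents one.

## Region classification

Four BED tracks are resolved into a five-class partition with fixed
priority satellite > tandem repeat > repeat element > low mappability;
uncovered bases are `normal`. The implementation is a boundary sweep with
a priority heap: O((n log n) per chromosome in the number of intervals,
independent of chromosome length. Book-ended same-class pieces are merged
*after* priority resolution (merging before could let a lower-priority
class absorb a boundary). Intervals exceeding the chromosome are rejected
rather than clipped — silent clipping hides upstream coordinate errors.
Points (e.g. variant positions) are annotated by the class at their start
coordinate, which is deterministic and matches VCF anchoring.

## TR catalogue filtering

Loci keep the standard discovery bounds: motif length in [10, 100] bp and
array length in [50 bp, 10 kb]. A locus is excluded when any *single*
repeat-element interval covers ≥ 50 % of it; coverage is deliberately
per-feature, not cumulative, mirroring per-pair `bedtools intersect -f`
semantics, so two disjoint 30 % overlaps do not exclude.

## Coordinate liftover

**Exact (base-level graphs).** The locus boundaries are expressed as
offsets within anchor segments on the reference path; the same offsets
applied to the anchors' occurrences on the target path give the
translated interval. Anchors are the segments containing the base just
outside each boundary, expanded outward up to `flank` bp (default 500 —
larger than any permitted motif, small enough to stay local) when the
nearest anchor is absent from the target. Among orientation-consistent
occurrence pairs the minimal positive span wins; an exact status requires
unique nearest anchors, a tie is reported as `ambiguous`, a missing
anchor as `failed`. Anchors are never taken inside the repeat interval:
repeat-internal segments recur on cyclic paths and are the classic source
of grossly mistranslated intervals, which is also why `size_delta`
(target minus reference length) is carried on every result as a
mistranslation diagnostic. Ambiguity is reported, not resolved by further
heuristics; downstream genotyping treats ambiguous loci as no-calls.

**Bubble-anchored (SV-level graphs).** A TR overlapping one or more
bubbles is translated by replacing each spanned bubble's reference
interior with the called traversal and carrying the TR's reference
offsets relative to the bubble flanks unchanged; several spanned bubbles
are merged with the intervening reference. The result is a splice plan
(reference pieces + traversal segments) from which sequence and length
follow; coordinates are approximate by construction, hence at best
`anchored`. No bubble overlap means the locus is simply not examinable at
SV resolution (`failed`), as is a MISSING traversal.

## Motif counting

The copy number is the number of non-overlapping windows within edit
distance `⌊rate·|M|⌋` of the motif `M` (default rate 0.25), found by a
greedy left-to-right scan with shortest-window preference: at each
position one DP over the motif × window rectangle yields the distance of
every window prefix, the shortest admissible window is consumed, and the
scan resumes after it (or advances one base on no match). Choices worth
recording:

* **Per-occurrence budget**, not a global one: error tolerance is meant
  to absorb divergence *between repeat units*, and a unit-wise budget
  cannot be exhausted by one bad unit.
* **Non-overlapping, forward strand only**; extraction orientation-
  normalizes the sequence to the reference strand first. Counts are
  integers; partial trailing units do not count.
* The greedy shortest-window rule means matched window boundaries drift
  within an array (the first window of a clean array is `|M| − budget`
  long), but totals are exact: `count(M^k, M) = k` for non-degenerate
  motifs, a tested invariant up to k = 100. Appending a clean copy to an
  arbitrary sequence adds at least one occurrence and can add two when a
  window spanning the junction also matches — an inherent property of
  bounded-error matching, covered by the property tests.
* **Degeneracy** is flagged via Hamming distance between the motif and
  its rotations by less than half its length (an AT-repeat rotated by its
  period is identical; a random motif mismatches ~¾ of positions). Edit
  distance is the wrong tool for this test because any string is within
  `2s` edits of its own shift by `s`. Degenerate motifs still count
  deterministically under the greedy rule but their occurrence boundaries
  are not meaningful.
* `N` never matches anything, including another `N`.

A locus is *genotypable* when every assembly's liftover resolved
(`exact`/`anchored`) and a *VNTR* when additionally at least two distinct
counts occur.

## Concordance metrics

Agreement categories (identical in all methods / in ≥ 2 / in none) are
computed over loci genotyped by every method in every assembly; a locus
is identical for a method pair only if all assemblies match exactly.
Correlations are squared Pearson/Spearman with pairwise deletion of
missing values; constant vectors raise instead of returning 0, since a
silent 0 would be indistinguishable from true discordance. Count trees
use neighbour joining on Manhattan distance normalized by the number of
shared loci — chosen over hierarchical clustering because NJ exactly
reproduces additive metrics, which makes topology recovery testable;
assemblies are processed in name order for determinism and negative NJ
branch lengths are clamped to zero. No claim is made that any particular
published tree topology is reproduced.

GAF summaries define edit rate as Σ edit distance / Σ alignment block
length and query coverage as Σ aligned query span / Σ per-query length
(each distinct query counted once), so multiple equally scored alignments
push coverage past 100 % while unaligned sequence lowers coverage but not
the edit rate. Records without an NM tag contribute to coverage only and
are flagged. Optional grouping by a region partition requires query names
of the form `chrom:start-end` (the convention produced by region-split
FASTA extraction), annotated at the query's reference start.

The allelic-imbalance test is the exact two-sided binomial p-value at
null 0.5 under the minlike rule (sum of probabilities of all outcomes no
more likely than the observed count), delegated to
`scipy.stats.binomtest` and cross-checked in the tests against a direct
binomial-coefficient summation.

## Synthetic fixtures

The generator emulates a pseudo-assembly study design: a uniform-random
200 kb chromosome with 20 planted TR arrays (motifs 10–24 bp, drawn
non-degenerate; reference copy numbers 4–60) and five derived assemblies,
each carrying per-locus copy-number deltas (a mix of none, ±1 unit, and
SV-sized changes of ≥ ⌈50/|M|⌉ units), 40 SNPs, 8 small indels (≤ 20 bp),
2 insertions and 2 deletions of 50–300 bp, and per-unit motif noise (one
mid-unit substitution per unit with probability 0.2, strictly below the
counting budget). Everything is deterministic given the seed; the default
seed is 7.

Variants are planted non-overlapping within *and across* assemblies,
≥ 1 kb from chromosome ends and ≥ 10 bp apart, so graph construction is
exact bookkeeping: breakpoints are shared, each variant is one bubble,
and the base-level graph is lossless by construction (every assembly's
path sequence equals its FASTA byte-exactly — a tested invariant). The
SV-level flavour keeps only variants whose allele lengths differ by
≥ 50 bp and emits truthful per-assembly bubble-call records; variants
from different assemblies at one interval form a single multi-allelic
bubble with one call record per assembly.

What the generator does **not** emulate: realistic mutation spectra,
overlapping/nested variation, inversions, repeat-mediated misassembly,
N-gaps, or alignment ambiguity. Passing the recovery tests therefore
demonstrates the correctness of the bookkeeping, liftover and counting
machinery under clean conditions — not robustness to the aligner- and
builder-induced artifacts of real pangenomes, where anchor ambiguity and
bubble curation errors dominate.

## Problem sizes and tolerances

The default test and acceptance conditions are the desk-scale spec above
(200 kb × 5 assemblies × 20 loci), 1,000-instance random suites for the
motif-counter oracle, region-partition oracle, identity liftover and
coordinate round trips, and a 4-taxon additive matrix for tree recovery.
Floating-point comparisons use relative tolerances of 5 × 10⁻³ for the
published binomial p-values (3 significant figures) and exact or 1 × 10⁻⁹
comparisons elsewhere; fractions in a partition must sum to 1 within
1 × 10⁻¹².

## Known limitations

* Exact liftover assumes the target path shares the anchor segments with
  the reference; heavily rearranged or deeply diverged regions degrade to
  `anchored`/`failed` rather than being recovered.
* Bubble-anchored liftover trims flank offsets in target coordinates, so
  a TR starting inside a bubble whose allele differs at its 5′ end can be
  off by the local drift; counts there are only guaranteed within the
  size of that drift.
* The motif counter is quadratic in motif length per scanned position;
  fine for catalogue-bounded motifs (≤ 100 bp) and arrays (≤ 10 kb), not
  intended for megabase-scale scanning.
* Graphs are held fully in memory; chromosome-scoped inputs are expected
  for mammalian-scale pangenomes.
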