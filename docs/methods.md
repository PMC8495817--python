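# Methods

This note documents the models, definitions and numerical choices behind
barcodekit, in the order data flows through the package.

## Pairwise identity

All identity computations use one aligner: optimal semi-global alignment
(terminal gaps free in either sequence) under blastn-like scoring — match
+2, mismatch −3, gap open −5, gap extend −2, a gap of length *g* costing
`open + g·extend`. The dynamic program is exact (full Gotoh matrices, no
seeding heuristics); library-scale inputs are small enough that exactness
is affordable, and it removes any heuristic dropout from the decision
rules. Among equal-score alignments the canonical one has the fewest gap
columns (folded into the DP objective), then gaps placed leftmost
(traceback prefers substitution over a gap in the subject over a gap in the
query).

Percent identity is `100 · identical columns / columns`, the denominator
excluding columns where either row has a terminal gap and including
internal gap columns; an ambiguity code matches only the exact same symbol.
Coverage is the fraction of the query's residues inside the non-terminal
region; identity is symmetric, coverage is not. Each unordered pair is
aligned once in a canonical orientation so identity tables are exactly
symmetric even where co-optimal alignments disagree; both orientations'
coverages are read off that one alignment. Decision rules compare the exact
integer (identical, denominator) pairs as rationals — "exactly 100%" means
`identical == denominator`, never a float test.

**Evidence floor.** Two sequences past saturation (a fast spacer across
families) have no positively-scoring full-length alignment, and the optimal
semi-global alignment degenerates to a few-column chance overlap at
near-100% identity. A real BLAST search reports nothing for such pairs
(word size, E-value), so neither do we: a comparison whose aligned region
spans fewer than `MIN_HIT_COLUMNS = 30` columns yields no hit, in the
all-to-all tables, in curation similarity and in ASV assignment. This is a
hit-existence floor, not a coverage filter; full-length barcode comparisons
are never affected.

## Barcode resolution

A query specimen is correctly assigned when its identities point to its own
species. If no conspecific hit exists (singleton in scope), the query is
correct iff no heterospecific hit is exactly 100% identical. Otherwise, with
I = max conspecific and X = max heterospecific identity, the query is
correct iff I > X, or I = X under the default tie policy (`pass`,
encoding the permissive "similar or higher" reading); the strict `fail`
policy is offered alongside. A species is IS when every query agrees
(aggregation `all_queries`, the default; `any_query` is available), NIS
otherwise, NA with no sequence in scope. Combined-marker scope pools
identical/denominator counts over the markers a pair shares; a specimen
with at least one of the markers counts as an accession. Under reduced
sampling the library is first restricted to species with every marker,
while the species universe stays complete, so excluded species surface as
NA.

Percentages are rounded half-up to two decimals, which reproduces the
recomputable printed cells of the survey tables this layout mirrors. Two
source inconsistencies are resolved as follows: the combined complete-row
%IS as printed divides by total species rather than by IS+NIS — we
implement the footnote formula (IS/(IS+NIS)) and do not reproduce that one
cell; one coverage percentage in the source text implies truncation where
every table cell implies half-up — half-up is used throughout.

## Phylogenetic resolution

Monophyly is defined on unrooted bipartitions: a species with ≥ 2 tips is
monophyletic iff some edge (pendant edges included) separates exactly its
tips. Supports live on internal edges, written in newick as internal node
labels; where a rooted binary file duplicates the root split across the two
root-child edges, the label of the node whose descendants are exactly the
species is preferred. A species attached to one polytomy without an
exclusive edge is non-monophyletic; a species covering all tips, or whose
separating edge carries no label, is monophyletic with no support and never
counts toward MS. MS requires support ≥ `min_support` (default 70);
NMS = SMA − MS. The threshold is inclusive (≥ 70 counts).

The built-in tree builder is neighbor joining on p-distances (gap-free
column pairs; negative branch lengths clamped to 0) with nonparametric
column-bootstrap supports: each replicate resamples alignment columns with
replacement, rebuilds, and an original bipartition's support is the
percentage of replicates containing it. This is a deliberately light
stand-in so the pipeline runs end-to-end; externally inferred ML trees are
first-class inputs via newick.

## Metabarcoding

Assignment: each ASV is aligned (as query) against every reference record
of the chosen marker; the best hit maximizes (identity, coverage) as exact
rationals. The ASV is assigned to the best hit's species when identity ≥ 95
and coverage ≥ 70 (defaults), `below_threshold` otherwise, and `ambiguous`
when equally best hits span several species (no genus-level fallback).

Curation: ASVs are processed in increasing total-count order (ties by id).
A daughter merges into the best eligible parent — more total reads,
similarity ≥ 84%, present in ≥ 95% of the daughter's samples, per-sample
parent/daughter ratio (minimum, by default) ≥ 1 — choosing the highest
similarity, then the larger parent. Counts are moved, never dropped, so
per-sample read totals are invariant; gates are evaluated against the
current (accumulated) table, and merge chains resolve transitively to the
final survivors after the single pass. Abundance reports divide each
species' assigned counts by the sample's total assigned counts; samples
with nothing assigned are flagged rather than zero-filled.

## Synthetic data generator

The generator reproduces the *structure* the analysis assumes, not
sequencing realism. A ranked taxonomy (orders grouping families, default 2
per order) is drawn with the singleton-rich species-abundance pattern of
the emulated field collections: a species has one specimen with probability
0.62, otherwise 2–3. Sequences evolve by Jukes–Cantor down the hierarchy
(family → genus → species → specimen) from one random root per marker;
across total branch length *d* a site differs with probability
`(3/4)(1 − e^(−4d/3))`, the closed form every calibration test checks
against.

Defaults, chosen once as field-realistic and then left alone:

| parameter | default | why |
|---|---|---|
| branch lengths (subs/site, rate 1) | family 0.15, genus 0.08, species 0.04, intraspecific 0.003 | species separation an order of magnitude above intraspecific variation, as in a resolvable flora; congeners clearly distinct on the fast marker (≈ 67% identity) yet far below the 84% curation gate |
| slow marker | 550 nt, rate ×1, no indels, 12% missing | plastid-gene-like: long, slow, near-universal |
| fast marker | 450 nt, rate ×5, single-site deletion rate 0.002/branch, 12% missing | nuclear-spacer-like: smaller amplicon, fast, mildly length-variable |
| taxonomy shape | 25 families × 1–3 genera × 1–3 species | ≈ 100 species, matching the scale of the emulated survey's marker test |
| bulk samples | 6 plots, 8–15 species each, lognormal σ = 1 around 300 reads | plot-structured composite samples at a scaled-down read depth |
| erroneous ASVs | probability 0.3, 2 substitutions, 10% of parent abundance | daughters sit inside every curation gate by construction |

The source survey states no quantitative divergences; these are free
parameters of the generator and the numbers above are this package's own
choices. Missingness is independent per record; the fast marker's deletions
are recorded so each marker also has an exactly aligned matrix (no
alignment step is needed or provided — multiple alignment is out of scope).
Random streams are seeded per stage (taxonomy, sequences, missingness,
plots) from the config seed, so every artefact is a pure function of its
config.

What passing on synthetic data does *not* show: robustness to alignment
error, paralogy, chimeras, primer bias, incomplete reference coverage, or
rate variation among sites/lineages (the generator is strict JC on a
rank-balanced tree). Results on real libraries depend on those factors;
the synthetic suite demonstrates correctness of the decision rules and
bookkeeping, not field performance.

## Degenerate inputs and tie-breaks

Empty alignments (no positively-scoring overlap) report identity and
coverage 0 and never form hits. Species statuses always partition the
universe (IS+NIS+NA = total, asserted at run time). %MS with SMA = 0 is
reported as undefined, not 0. NJ requires ≥ 3 taxa; bootstrap requires a
positive replicate count. Curation ties (equal similarity and abundance)
break by ASV id; assignment ties across species are surfaced as
`ambiguous` rather than broken arbitrarily.

## Known limitations

* The aligner is quadratic per pair; all-to-all tables over a few hundred
  specimens take about a minute. Sequences are capped at 2,000 nt.
* The NJ + bootstrap builder is a stand-in; its supports are not comparable
  to ML rapid-bootstrap values on real data.
* Curation follows the single-pass, current-counts reading of the
  co-occurrence algorithm; pathological tables could admit a still-mergeable
  pair after the pass (the fixed point is verified on the synthetic
  conditions, not proven universally).
* Combined-marker pooling weights markers by their aligned lengths, which
  is the concatenation convention, not an information-weighted average.
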