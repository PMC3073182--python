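# Methods

This note documents the models and procedures implemented in `pdsenet`, the
design choices made where more than one reasonable construction exists, and
what the synthetic validation does and does not establish about real data.

## Enrichment scores over ranked instances

A treatment instance is a total ordering of the gene (probe) universe by
treatment-to-control expression ratio. For a gene set *S* (|S| = N_s) in a
list of N genes, the running sum adds `c_hit = sqrt((N − N_s)/N_s)` at each
member and `−c_miss = −sqrt(N_s/(N − N_s))` at each non-member. The
increments are zero-sum: the walk ends at exactly 0, and the partial sums
form a discrete bridge. The enrichment score is

    ES = max(0, max_j Sum_j),

the maximum deviation from zero attained by the walk. Down-regulation is
scored by walking the reversed list.

**Why the maximum, not the extremum of either sign.** The walk of a
bottom-concentrated set dips strongly negative, so a signed
max-|deviation| statistic already "detects" bottom-concentration on the
forward list — under that convention the reversed-list pass would be
redundant, and the null distribution of the signed score is bimodal
(±sup of the bridge). That bimodality inflates the median-MAD scale by a
factor of several, which makes the t > 3 edge filter essentially
unreachable even for strongly planted signals. With the one-sided maximum,
the null is the one-sided bridge supremum (P(sup > x) ≈ exp(−2x²/N)), the
MAD is small, direction is carried entirely by which list is walked, and
the reversed-list pass is what gives down-regulation meaning. This package
therefore uses the one-sided maximum; ES is non-negative by construction
and bounded by `sqrt(N_s (N − N_s))`.

**Increment convention.** Among zero-sum conventions that differ by a
positive per-set constant (e.g. 1/N_s vs sqrt-based increments), the
downstream network is invariant: median and MAD scale together, so every
t-score — and hence the edge set — is unchanged. A property test asserts
this invariance.

**Implementation.** The running sum strictly decreases between members, so
its local maxima occur immediately after a hit; ES is evaluated on those
candidates only (O(N_s) per pair after position lookup), with the final
position excluded — its value is exactly 0 in exact arithmetic and is
supplied by the clamp, avoiding a ±1 ulp artifact when the last gene is a
member. A full-trajectory `running_sum` is kept for diagnostics and the
zero-sum test. Sets with no overlap with the universe raise a specific
error; in matrix mode they are skipped with a warning. Sets covering the
whole universe are degenerate (c_miss undefined) and rejected.

## Robust standardization and the edge filter

Per (gene set, direction), scores across instances are centered at the
median and scaled by 1.4826·MAD (the consistency factor for σ under
normality); t = (ES − MED)/(1.4826·MAD). Rows with MAD = 0 (constant
scores) are flagged degenerate and excluded rather than producing infinite
t — a constant row carries no evidence. Groups need at least 2 instances.

Edges keep instances with **t strictly greater than 3.0** (≈ p = 0.001
one-sided under normality) whose set has **at most 30 genes** counted
against the supplied universe ("fewer than 31"); larger terms are too broad
to interpret. With several instances per drug the default is the union
(an edge per passing instance; drug-level presence if any passes), with a
`max_t` mode keeping only the best instance per (drug, process, direction).
The case analyses this mirrors used single instances, so multi-instance
aggregation is genuinely open; union is the more permissive, simpler
default.

**Contamination caveat.** The median/MAD are taken over *all* instances,
including truly perturbed ones. They are robust up to a point: if a large
fraction of instances carries the same perturbation (≳ 15–20%), the MAD
inflates and power drops sharply. This matters when designing small
validation scenarios (see below) and would matter in real compendia if one
compound family dominated the instance set.

## Side-effect layer

Frequency descriptions are resolved as: `"X%"` → X/100; `"X–Y%"` → the
midpoint (deterministic and monotone in both endpoints); the qualitative
descriptors postmarketing → 0.001, rare → 0.001, infrequent → 0.01
(case-insensitive, configurable map); anything else is missing — unknown
descriptors are never guessed. Records with score ≥ 0.2 are kept
(**inclusive** boundary, exposed as a flag; the cutoff's strictness is not
canonical), records without frequency are dropped.

Drug labels are normalized against a synonym table (canonical id →
primary/synonym/brand names) by exact match after trimming and
lowercasing. Fuzzy matching is deliberately not offered: drug nomenclature
contains many near-collisions and a silent false merge corrupts the bridge.
Labels claimed by two or more canonical drugs raise an error listing the
collision; unmatched labels are dropped and counted.

## ABC merge, co-occurrence, and the permutation null

The two layers are restricted to drugs present in both (the bridge); an
empty bridge is an explicit error. For each side effect with TD ≥ 2 bridge
drugs, every (process, direction) hit by at least one of its drugs becomes
a candidate pair with score CD/TD. Scores are exact ratios; 2-decimal
rounding happens only in writers.

The null asks: if TD drugs were assigned to an effect at random, how many
would share a process? For each observed TD, TD drugs are drawn uniformly
without replacement from the bridge pool (TD held fixed — the degree
structure of the side-effect layer is treated as given), per-process
co-occurrence counts are recomputed against the **real** drug→process
layer, and the nonzero counts are pooled across processes and draws.
Pooling across processes matches the published form of the threshold table
(one threshold per TD, not per process) and mirrors candidate emission,
which also requires CD ≥ 1. The threshold for TD is the smallest c ≥ 2
with empirical P(null ≥ c) **strictly below** α (default 0.05, 1,000
draws); a +1-corrected estimator is available behind a flag but disabled
by default to match the strict "p < α" rule. If no count qualifies (tiny
pools, point-mass nulls) the TD is marked unattainable and nothing at that
TD is significant. Up- and down-regulated layers are scored independently
end-to-end, with independent RNG streams spawned from the pipeline seed.
An exhaustive-enumeration mode replaces sampling for small pools and
backs the sampled-vs-exact agreement test (total-variation distance).

Known limitation (inherited by design): all drugs weigh equally in CD/TD,
regardless of how many side effects or processes each drug carries.

## Literature matching (simplified harness)

The full text-mining stack (sentence segmentation, POS tagging, chunking,
and the path-based edit distance) consists of published third-party tools;
this package takes pre-extracted noun phrases as input and uses
**normalized Levenshtein similarity** — 1 − distance/max(len) after
lowercasing, two empty strings defined as identical — as the matching
kernel (edit distance via `edlib`). A phrase counts for a term when
similarity ≥ 0.55. Per-term counts form the literature ranking (raw counts
by default; per-effect normalization behind a flag, since the original
score normalization is not defined); ranking ties break lexically by GO id
for determinism. Top-n% overlap uses a `ceil(f·|ranking|)` cutoff.

A practical caveat measured during development: at threshold 0.55,
normalized edit distance is promiscuous on templated ontology-style
vocabularies — names sharing a long scaffold ("… catabolic process") match
each other, so counts separate similarity *neighborhoods* rather than
individual terms. The synthetic generator therefore prefers mutually
dissimilar term names (greedy selection under the 0.55 threshold) so that
the evaluation harness is exercised in a regime where it can discriminate.

## Synthetic scenarios

The generator emulates the four inputs at desk scale with planted
structure. Defaults: 2,000 genes, 200 gene sets of 5–30 genes, 74 drugs ×
1 instance, 30 side effects, 4 drugs per effect, planted strength 0.8,
30 decoy links.

* **Planting model.** For each planted (drug, set, direction),
  `round(strength · N_s)` of the set's genes are placed at uniformly random
  positions within the top decile of that drug's list (bottom decile for
  down); all other ranks are uniformly random permutations. The decile
  placement is a generator artifact — no generative model of real
  drug-responsive ranks is claimed — chosen to make planted ES large while
  keeping the walk statistics well defined. Overflowing a decile (too many
  planted genes for 10% of the universe) is a configuration error.
* **Plantable sets.** Planted processes are drawn only from sets with ≥ 8
  members (`min_planted_set_size`). At strength 0.8 a 5-gene set plants 4
  genes, whose decile ES sits almost exactly at the null's
  MED + 3·1.4826·MAD boundary; recovery there is a coin flip. That is a
  property of the method's power at small set sizes, and the validation
  scenario is built where the method has power, leaving the power boundary
  itself documented rather than baked into flaky tests.
* **Effect structure.** Each planted effect gets one process, one
  direction, and a drug group (default 4); all group drugs are planted
  with that process, so drugs sharing a planted effect share a planted
  process. Planted drug–effect links draw frequencies from {25%, 50%, 75%}
  (all pass the 20% filter); decoy links draw from {0.1%, 1%, 10%} (all
  fail), exercising the filter in both directions.
* **Reproducibility.** One seed sequence per scenario, spawned per
  sub-generator (sets, truth, one stream per rank column, side effects), so
  changing one dimension does not reshuffle unrelated parts.
* **Name aliasing.** `make_synonym_collisions` rewrites a fraction of
  side-effect drug labels to brand aliases of the same canonical drug,
  stress-testing normalization: the merge must recover the same drug set.

**What the generator does not model:** correlated gene expression,
cell-line or dosage effects, probe→gene multiplicity (a rank-collapsing
mapping hook exists but the synthetic path works on genes directly),
realistic side-effect co-reporting structure, or the 6,100-instance scale
of real compendia. Passing the planted-recovery suite shows the pipeline's
plumbing and statistics behave as designed under its own assumptions; it
is not evidence about sensitivity on real expression data.

## Problem sizes and runtime choices

The integration fixture uses 300 genes / 40 sets / 40 drugs / 6 effects —
40 drugs so that planted instances stay near 10% of each score row,
keeping the median-MAD standardization in its working regime (see the
contamination caveat). Zero-signal false-positive checks run 50 seeds of a
12-drug version with 300 permutations; the full default scenario runs with
1,000 permutations. The acceptance script reruns the default scenario, the
50-seed zero-signal sweep, and a 10,000-draw null-agreement check in a few
seconds on one core.

## Degenerate inputs and tie-breaking summary

* ES of an anti-correlated set (walk never positive) is 0, not negative.
* Positional ties cannot change the ES value (the maximum is a value, not
  an index); ranking ties in the literature module break lexically.
* MAD = 0 rows, empty gene sets, whole-universe sets, empty bridges,
  TD larger than the pool, and unknown frequency descriptors all fail
  loudly or are excluded with a logged warning — never silently imputed.
* All writers emit deterministic row order; identical config + seed gives
  byte-identical outputs.
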