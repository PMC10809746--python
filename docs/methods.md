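# Methods

## Problem and model

Clonally related BCR sequences share a junction of one length whose
nucleotide differences reflect somatic hypermutation; clonal grouping is
therefore formulated as single-linkage clustering of equal-length junctions
under a normalized Hamming distance (HD) cutoff. `anchorclust` computes the
same partition as direct single linkage would, but only within small
subclusters produced by a divide-and-conquer front end; the approximation it
accepts is that clusters are never merged across subcluster boundaries.

## Anchor selection by point packing

Within one junction-length group, anchors are sequences whose pairwise HD
all satisfy `d_min = ceil(ratio × L)` (the ceiling guarantees the configured
ratio is a true lower bound). The greedy lexicode scan (`conway_lexicode`)
processes candidate points in order and accepts a point iff it is at least
`d_min` from every accepted point — deterministic given the order, and
order-sensitive, which the evolutionary layer exploits:

- **Initialisation:** `population_size` (default 1000) packings, each the
  greedy scan of an independent random shuffle of the candidate points.
- **Variation:** two uniform-randomly chosen parents are unioned, augmented
  with `random_material_rate` (default 50) points sampled uniformly without
  replacement from the candidate pool, shuffled, and re-filtered through the
  greedy scan. Injected points come from the input pool — anchors must be
  real sequences so the distance vectors reference observed space.
- **Replacement:** steady state; the offspring replaces the smallest
  population member if strictly larger (fitness = packing size). The best
  packing is returned after 50 offspring, or earlier after 20 offspring
  without improvement.

These loop choices (uniform parent selection, replace-worst, size fitness,
offspring-count stopping) were design decisions of this package; each is
exposed through `PackingParams`. The defaults — ratio 0.6, population 1000
— follow the regime in which the method performs best; the random material
rate default of 50 sits at the midpoint of the range the method is known to
tolerate.

Candidate pools are deduplicated before packing. The packing kernel packs
bases into 2-bit fields of 64-bit words so a pairwise HD is an XOR plus
popcount; a numba-compiled scan additionally skips points already within
`d_min` of an accepted anchor (they can never be accepted). A pure-numpy
fallback implements the identical scan; tests assert exact agreement.

## Recursive BIRCH partitioning

Each sequence in an oversized group is embedded as its vector of normalized
HDs to the anchors. Vectors are normalized (divided by L) because the BIRCH
merge radius of 0.5 and the clonal cutoff of 0.12 are only dimensionally
meaningful on a [0, 1] scale. BIRCH builds a clustering-feature tree
(threshold = radius, branching factor 50) on a uniform random sample of
`ceil(fit_fraction × n)` rows, then assigns every row to the nearest final
subcluster centroid — out-of-sample assignment is by nearest centroid, not
tree insertion. The global step agglomerates subcluster centroids into as
many clusters as anchors; empty parts are dropped. `fit_fraction` defaults
to 1.0 for groups of up to 10,000 rows and 0.10 above that, following the
observation that a 10% sample suffices to fit the tree.

Parts larger than the size threshold are re-packed and re-split. Degenerate
rounds — fewer than two anchors, or a split returning one part — relax the
ratio in steps of 0.1; below 0.3, or at the depth bound (30), the group
becomes a *forced leaf*. Forced leaves are still clustered exactly, via a
blocked union-find over the threshold graph (memory ~block × n instead of
n²/2), so termination never costs correctness. Leaves always partition the
input; a conservation check is part of the test suite.

## Single linkage and assembly

Leaves up to 8,000 sequences use `scipy` condensed distances
(`pdist(…, "hamming")`, single-linkage, `fcluster` cut at the cutoff);
larger leaves use the blocked connected-components path, which yields the
same partition (cross-checked in tests). The cutoff comparison is inclusive
(pairs at exactly the cutoff merge). Cluster ids are made globally unique
across length groups; no cluster ever spans two junction lengths.
`audit_cross_leaf_pairs` reports, on sampled rows, how many within-cutoff
pairs the leaf-boundary approximation severs.

Every (V/J group, length) stratum draws its own random substream
`default_rng([seed, group, length])`, so results are independent of
processing order and worker count; the test suite compares 1-worker and
2-worker runs byte for byte.

## V/J grouping

Two sequences are linkable when they share at least one V gene AND one J
gene (relaxable to one side); multi-annotated sequences chain groups
greedily, i.e. groups are connected components of the shared-gene graph.
Gene names are compared allele-stripped (text before `*`) by default, so
multi-allele annotations of one gene do not split clones. VJ-Pre applies the
components before distance clustering; VJ-Post re-splits each distance
cluster into components (never merges; idempotent). Records lacking V or J
calls bypass the grouping into a catch-all group so unannotated data still
clusters.

## I/O and bookkeeping

AIRR-style TSV (columns `junction`, `v_call`, `j_call` by default,
overridable) and plain FASTA are read; sequences are uppercased, records
with non-ACGT characters dropped and counted, and exact duplicates —
identical junction plus identical V/J call sets, or junction-only via a flag
— collapsed into a `duplicate_map` keyed by the retained record's id.
Duplicates are defined globally across the input, re-expanded with their
representative's cluster on write, and the identity `input = retained +
ambiguous + duplicates` is asserted per run.

## Synthetic repertoires

The simulator emulates clonally structured data: per clone, one junction
length, a uniform-random germline, and members generated by attaching each
new node to a random existing node of depth < `lineage_depth` and mutating
every site independently at `per_site_mutation_rate` (uniform substitution
to a different base). Expected within-clone divergence per site is bounded
by `1 − (1 − r)^(2d)`; between-clone distances concentrate near 0.75
(uniform germlines). It does **not** model germline V/D/J segment structure,
hypermutation hotspots, indels, or realistic lineage topologies, so passing
tests demonstrate correct recovery of well-separated clones, not performance
on real repertoires where clone boundaries are fuzzier. Optional gene-call
simulation (per-clone random V/J, configurable multi-annotation chance)
exercises the V/J grouping; labelled mixtures concatenate independent
repertoires so clones are label-pure by construction.

## Reference evaluation protocol

`anchorclust.protocols` fixes the study conditions used by the validation
suite and `scripts/acceptance.py`: repertoires of 250 clones with fixed
clone size 38 before deduplication (~5,000 unique junctions), rate 0.015,
depth 3. The ratio/threshold sweeps use two length strata (48, 51) so each
length group (~2,500 sequences) exceeds the default size threshold of 1,000
and the packing/BIRCH path is genuinely exercised rather than short-cut to
plain single linkage; the fitting-fraction sweep uses the five-length layout
(48–60) and averages per-length F-measures unweighted (pair pooling is the
default elsewhere). These sizes keep the full grids to a few minutes on one
CPU while leaving one to two recursion levels per group.

## Numerical and degenerate-case choices

- Distance kernels are exact integer counts; normalization divides by L
  once at the end. Threshold comparisons add 1e-12 to absorb float division.
- Zero-denominator metric conventions: sensitivity 1 with no related pairs,
  precision 1 with nothing co-clustered, F-measure 0 when both are 0.
- Empty inputs raise explicit errors at read time; an empty table yields an
  empty result, a single sequence a single cluster.
- `d_min` rounding is `ceil`; a single candidate point always packs to size
  1; unsatisfiable constraints yield size-1 (or empty) packings rather than
  errors.

## Known limitations

- Clusters are never merged across leaf boundaries; with closely related
  clones (within-clone divergence approaching the cutoff) the partitioner
  can split a clone and cost sensitivity. The audit helper quantifies this.
- Hamming-only: similar junctions of different lengths are never grouped
  (no Levenshtein support).
- Nucleotide BCR junctions only; amino-acid or TCR data would need
  different distances and thresholds.
- The evolutionary packing loop is a reconstruction exposing its choices as
  configuration; other selection/replacement schemes may pack differently,
  though any valid packing satisfies the same distance invariant.
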