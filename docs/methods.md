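# Methods

This note documents the model implemented by `blockspec`, its assumptions,
the parameters that matter, and the decisions taken where the design was
genuinely open.

## Data model

A cleavage event is an 8-symbol window over the 20 standard amino acids,
positions P4..P1 | P1'..P4' around the scissile bond.  Windows that extend
past a protein terminus are padded with `-`; gaps are only legal as a
contiguous prefix and/or suffix because a cleavage window is a contiguous
substrate stretch.  Ambiguity codes (B, J, Z, X, U, O) are rejected by
default; `read_substrate_table(..., on_ambiguous="drop")` discards such
windows with a logged warning instead.  Windows are positional objects:
no alignment or sliding is ever performed, because every window is already
anchored at the bond.

## Redundancy removal

Database-derived substrate collections over-represent well-studied
substrates.  Two filters run before any statistics:

1. **Length filter** (`min_residues = 2`): a window carrying fewer than two
   real residues is uninformative about successive-position cooperation.
2. **Greedy similarity filter** (`threshold = 0.875`): similarity between
   two windows is the fraction of the 8 positions at which both carry the
   same amino acid.  Gap–gap positions do not count as matches — shared
   absence of data is not evidence of similarity.  The filter builds the
   conflict graph (edge iff similarity ≥ threshold, i.e. ≥ 7/8 identical
   positions at the default) and repeatedly deletes the window with the
   most conflicts, recomputing degrees after each deletion, until no edge
   remains.  Ties are broken by deleting the window that appeared later in
   the input, which makes the procedure deterministic.  Highest-degree-first
   deletion (Hobohm-style) greedily maximises the retained set.  The
   guarantee after filtering: every retained gap-free pair differs at ≥ 2
   positions.  The pair scan is O(n²) in time and memory, acceptable for
   the ≤ ~10⁴ windows per protease that curated databases yield.

The exact deletion order of a greedy filter is underdetermined (different
orders can retain different, equally valid sets); the order above is this
package's fixed choice.

## Block entropies

Block B_k covers P_k..P1, block B_k' covers P1'..P_k' (k = 1..4).  A window
contributes its k-mer to a block only when the whole span is gap-free;
truncated windows still inform the blocks they do cover.  Whether truncated
windows should be dropped entirely or per block was an open choice;
per-block exclusion retains the most data.  The entropy of a block is the
plug-in Shannon estimate over the k-mer frequencies, in bits, with
frequencies normalised by the block's own contributing total so that
gap-excluded windows do not distort the distribution.  No small-sample
bias correction (Miller–Madow etc.) is applied.  An empty block makes the
entropy undefined and raises an error naming the block.

On gap-free data the profile is monotone under refinement
(E1 ≤ E2 ≤ E3 ≤ E4, primes likewise) because a k-mer distribution refines
its (k−1)-mer margin; with gaps the contributing subsets differ per block
and the inequality may not hold.

## Distance matrix

Profiles are compared by the unweighted Euclidean distance over the 8
entropies.  The matrix writers round to 3 decimals (CSV with labelled
axes, or square PHYLIP); full double precision is kept internally.

## Prominence testing

For each block of one protease:

* **Background model.** Empirical residue frequencies of the protease's own
  filtered windows, per position by default (`pooled` available).
  Per-position preserves the positional composition, so a prominent call
  means *cooperation between successive positions beyond composition* — a
  single-residue block (B1/B1') can essentially never be called against its
  own composition, which is the intended reading.
* **Simulation.** Each of `reps = 1000` repetitions draws a gap-free
  background set of the same size as the experiment set, every position
  sampled independently from the model.  Repetition r uses the r-th child
  of `numpy.random.SeedSequence(seed).spawn(reps)`, so results are exactly
  reproducible and repetitions are order-independent.
* **Test.** For every distinct combination observed at the block, the 2×2
  table (a = experiment windows whose block k-mer equals it, b = remaining
  contributing experiment windows, c/d = same for the simulated set) is
  tested with a one-sided Fisher's exact test: the tail sum over tables
  with a' ≥ a of the hypergeometric point probability
  (a+b)!(c+d)!(a+c)!(b+d)!/(a!b!c!d!n!), computed in log-space with a
  precomputed log-factorial table.  One-sided, because the question is
  over-representation; a two-sided test would also flag depletion.
* **Calling.** Bonferroni within the block: a repetition votes for a
  combination when p < α/N, with N the number of distinct combinations
  observed at that block (the most local reading of "per block"
  correction).  A combination is prominent when votes > reps/2 — strictly
  more than half, so at even reps an exact tie is not prominent.  The
  median p across repetitions is reported for ranking only.

"Contains the combination" means the window's block k-mer equals it
exactly; there is no sliding match.  The background set size equals the
experiment set size, which keeps the two margins comparable — both this
and the per-position default are configurable because either convention is
defensible.

The one-sided p is non-decreasing in c at fixed a and margins (more
background hits, weaker enrichment); the implementation exploits this to
cache p-values over the small set of distinct (a, c) pairs that occur
across repetitions.

Summaries: per block, the fraction of the set's windows whose k-mer is any
prominent combination, binned into five shades ([0,0.2), [0.2,0.4),
[0.4,0.6), [0.6,0.8), [0.8,1]) with a distinct "none" state when the block
has no prominent combination; and across proteases, the percentage with at
least one prominent combination per block.

## PCA

Correlation PCA (not covariance): eigendecomposition of the 8×8 Pearson
correlation matrix of the entropy columns.  Eigenvalues sum to 8, variance
explained is eigenvalue/8 × 100, and components with eigenvalue > 1 are
retained (Kaiser criterion).  Loadings are eigenvectors scaled by
√eigenvalue, i.e. block–component correlations.  Each eigenvector's sign
is fixed so its largest-magnitude entry is positive, making output
deterministic.  No varimax (or other) rotation and no sampling-adequacy
statistic are computed: those calibrate a particular statistics product's
output rather than the method's core, so reported loadings are unrotated.
A warning is emitted below 9 rows, where an 8-variable correlation matrix
is rank-deficient or unstable.

## Synthetic data

`generate_substrate_set` emulates the structure of curated cleavage
collections: a compositional background (uniform over the 20 amino acids
by default, or any background model), planted block motifs, near-duplicate
windows, and terminal truncations.  Design choices:

* Plants overwrite the block span *after* background sampling in a
  uniformly chosen carrier subset of exactly `round(fraction × n)` windows
  (ties to even), so the carrier frequency is exact rather than in
  expectation and power analyses are deterministic in the effect size.
  Overlapping plants must agree on shared positions.
* Near-duplicates are appended copies of random originals mutated at
  exactly one position — the worst case for the redundancy filter.
* Truncations replace a terminal run of 1–3 positions (one end) with gaps,
  mirroring the terminus convention.

The default study conditions used throughout the tests are n = 300 windows,
planted carrier fraction 0.6, reps = 1000, α = 0.05 — a planted effect of
that size yields Fisher p-values far below α/N, so detection is expected in
every repetition, while uniform null sets stay clean under the Bonferroni +
majority-vote rule.  The caspase-3-like fixture (`caspase3_fixture`) plants
`DEVD` at B4 in 60 % of 300 uniform-background windows at a fixed seed.

What the generator does **not** emulate: realistic proteome composition,
protease families with correlated specificities, measurement noise in
cleavage-site assignment, or cleavage kinetics.  Passing tests therefore
demonstrate correctness of the computations and calibration of the testing
procedure under known ground truth, not biological conclusions about any
real protease.

## Numerical choices

* Entropies in bits (log₂); 0·log 0 = 0; empty block → error, never NaN.
* Fisher tails in log-space via a cached log-factorial table (exact
  integer enumeration cross-checks in the tests agree to 1e−12).
* Matrix output precision 3 decimals; entropy TSV 6 decimals.
* All stochastic stages take an explicit integer seed; derived substreams
  use `SeedSequence.spawn`, never arithmetic on the seed itself.

## Problem sizes

The test suite runs the full prominence procedure (reps = 1000) on sets of
300 windows across 25 seeds, exhaustively verifies the Fisher tail against
integer enumeration for every margin configuration with table total ≤ 60,
and checks entropy/PCA identities on hundreds of random sets; the whole
suite completes in about a minute on one CPU.

## Known limitations

* The plug-in entropy estimator is biased low at small counts; profiles of
  proteases with few substrates should be compared with caution.
* Prominence against the protease's *own* composition cannot flag
  single-position preferences (by design); use the pooled background if a
  compositional null is wanted.
* The greedy filter guarantees pairwise separation, not maximal retained
  set size (that problem is NP-hard).
* PCA loadings are unrotated and will differ in detail from
  varimax-rotated reports of the same data.
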