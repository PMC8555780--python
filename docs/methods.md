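# Methods

## The model

A somatic single-base substitution is represented with three flanking bases
on each side: an 8-character *mutation sequence* (left flank, original
base, new base, right flank), pyrimidine-collapsed so the original base is
always C or T. The universe of valid sequences has 2 × 3 × 4⁶ = 24,576
members. A *category* is an 8-symbol degenerate pattern: each symbol is a
single base, a dinucleotide IUPAC code (R, Y, S, W, K, M) or the wildcard
N; three-base codes are excluded. Non-joker patterns must have a concrete
C or T at position 4 and a 1- or 2-base set at position 5 disjoint from
position 4. A *categorization* is 96 such patterns, including exactly one
all-wildcard joker.

A mutation catalog `V` (samples × categories) is assumed to factorize
`V ≈ WH` with `H` row-stochastic signatures and `W ≥ 0` exposures. The
package searches for the categorization that maximizes the held-out
canonical correlation between `W` (refit on WES samples) and DDR gene
expression.

## Sequence-to-category assignment

Every sequence is assigned to its best matching category among those it
matches without mismatch, minimizing lexicographically:

1. **size** — the number of universe sequences matching the pattern
   (counted over the valid universe, so the joker's size is 24,576);
2. **span** — the inclusive position count from the first to the last
   non-N symbol (the two worked-example patterns both span 5);
3. **reach** — the largest flank offset of a non-N symbol from the
   mutation site (position i ∈ {1..3} counts 4−i; position j ∈ {6..8}
   counts j−5).

Smaller wins on all three criteria: a smaller category is more specific, a
smaller span more compact, a smaller reach closer to the mutation. Only
the direction of the reach criterion is fixed by the worked example; the
other two directions follow the same specificity-first logic. Residual
ties are broken uniformly at random from a dedicated seeded stream and
flagged *ambiguous*; the ambiguous fraction is the categorization's
conflict rate. The joker competes like any category but, having maximal
size, loses every contested tie, making it a pure fallback in practice.

The full 24,576-sequence assignment table is built once per categorization
(vectorized over a precomputed universe array) and reused for catalog
construction, opportunity counting and the transformation matrix; the GA
evaluates thousands of categorizations, so per-mutation pattern scans are
never used.

## Catalogs and opportunities

Mutation tables are 1-based (ICGC convention); BED regions are 0-based
half-open. Records are rejected — tallied, never fatal — on reference
mismatch, N in the ±3 window, window out of bounds, non-SNV alleles or
unknown chromosomes. Duplicate records are counted as-is unless
deduplication is requested.

Mutation opportunities count (position, alt) pairs: every position whose
full 7-mer window is N-free contributes three pyrimidine-collapsed
sequences, one per alternative base, so the opportunity vector `U` lives
in the same category space as `H`'s columns. Exome membership is decided
by the central base (flanks may extend outside the region). Signatures
learned on whole-genome data are moved to the exome regime by scaling each
entry by `U_WES,i / U_WGS,i` and renormalizing the row to sum 1; a
category unobservable in the source regime (U_src = 0) gets ratio 0 with a
warning.

## Factorization

KL-NMF minimizes the generalized Kullback–Leibler divergence
`D(V‖WH) = Σ V log(V/WH) − V + WH` by multiplicative updates. Entries of
W and H are initialized i.i.d. uniform, scaled to match V's mean; update
denominators are floored at 1e-12; iteration stops at relative objective
change < 1e-6 or 2000 iterations. The best of `n_restarts` random restarts
is kept (10 for evaluation reports, matching the out-of-sample protocol;
3 by default inside the GA fitness loop for tractability). H rows are
normalized to probability vectors with the compensating rescale absorbed
into W, leaving WH unchanged. An optional observation mask restricts the
objective to observed entries (weighted updates), used for rank selection.

Exposures for fixed signatures are per-sample non-negative least squares
(`scipy.optimize.nnls`).

**Rank selection (`cv2k_lite`).** The full cross-validation machinery for
choosing K is deliberately simplified here: a fraction (default 10%) of
catalog entries is hidden at random, a masked KL-NMF is fit on the rest,
and the generalized KL imputation error is scored on the hidden entries
(with WH floored at 1e-12 so a category driven to zero mass incurs a large
finite penalty rather than an infinite one); K* is the smallest candidate
within one standard error of the minimum mean error over repeats. The
selector reports its full error curve so an externally chosen K* can be
substituted.

## Fitness

Per dataset, per K in `[K*−2, K*+2]` (radius configurable, lower bound
clamped to 1): row-normalize the WGS catalog → KL-NMF → opportunity
renormalization to the exome regime → NNLS exposures on the WES catalog →
held-out CCA correlation against the gene-set expression matrix. The
fitness is the mean over K values and folds.

CCA is linear ridge-regularized CCA solved by the whitened-SVD
formulation: both views are z-scored on training statistics (constant
columns dropped), `reg = 0.1` is added to each view's correlation-scale
covariance diagonal, and the held-out statistic is the Pearson correlation
of the first canonical pair of projected test samples, averaged over a
seeded 10-fold split. The regularization value, linear kernel and
first-pair statistic are package choices; the number of components is
configurable. Fold partitions are fixed per dataset (one seed) so fitness
is comparable across individuals within a GA run.

K* is computed once per dataset at GA start and held fixed for all
individuals; recomputing it per categorization per generation would be
computationally prohibitive.

## Genetic algorithm

Defaults follow the tuned operating point: population S = 40, 100
ancestors truncated to S by average ranking, crossover rate q = 0.8,
mutation rate m = 0.05, selection power 5, interval-length concentration
c = 10, 500 generations, conflict threshold 1%.

**Ancestors.** Each category is an interval of `n_symbols` consecutive
non-N symbols, `n_symbols ∈ {3..7}` drawn with weights (1, c, 1, 1, 1) —
the weight notation is read as a categorical distribution with its mode at
4, the standard-category width. The interval start is uniform among the
starts covering positions 4 *and* 5 (an interval that missed position 5
would leave a wildcard new base, violating the disjointness rule); interval
symbols are uniform over the 4 single-base and 6 dinucleotide codes subject
to the position-4/5 constraints.

**Conflict maintenance.** After any change, while the ambiguous rate is
≥ 1%, the non-joker category involved in the most ambiguous ties is
replaced with a freshly sampled category (greedy; the match matrix is
updated incrementally rather than rebuilt). Residual ambiguity is resolved
by the random tied-winner rule.

**Selection.** Individuals are ranked 1 (worst) to S (best) per dataset;
the average ranking is the rank of the mean of per-dataset ranks (ties
broken by stable input order). The two best by average ranking pass to the
next generation unchanged, guaranteeing a non-decreasing top fitness. Each
remaining offspring draws a ranking uniformly from the per-dataset
rankings plus the average ranking, then draws parents with probability
proportional to rank^power; a parent is never crossed with itself
(without-replacement within the pair), while draws are independent across
offspring.

**Variation.** With probability q, crossover: a fraction u ~ (0, 0.4] of
the 95 non-joker slots is filled from the lower-ranked parent, the rest
from the higher-ranked one; duplicates collapse and any shortfall is
filled with fresh samples. Otherwise, mutation: each non-joker category
independently with probability m has one eligible symbol (non-N, excluding
the original base) moved between a single base and an intersecting
dinucleotide (e.g. A → M, K → G), keeping position 5 disjoint from
position 4; non-intersecting changes can only happen through a series of
such steps. Fitness values are cached by canonical pattern multiset, so
elites and unchanged offspring are never re-scored.

## Evaluation and reference comparison

Out-of-sample evaluation fits signatures on WGS samples only and scores
held-out WES samples: the KL reconstruction error of the NNLS fit (WH
floored at 1e-12) and the held-out CCA correlation per gene set, for each
K in the report grid `[2, max(k_ref, K*) + 2]`. Signatures over arbitrary
categories are compared to a reference catalog over the standard 96
categories through the transformation matrix `T` (row i = the distribution
of category i's sequences over the standard categories; empty categories
give zero rows, and any transformed mass lost that way triggers a
renormalizing warning). Matches above cosine 0.8 are reported best-first;
if none clears the threshold the single best match is reported and
flagged. Reference-signature prevalence is the raw mean of jointly refit
NNLS exposures across samples.

## Synthetic data generator

The generator emulates the assumed statistical structure end to end:

* **Genome** — i.i.d. bases at configurable GC (default 0.40, roughly
  genomic), with a random disjoint "exome" of 150 bp intervals. The
  default exome fraction is 0.25 — far larger than a real exome's share of
  the genome, a deliberate fixture-scale choice so the 200 kb toy genome
  still yields informative WES burdens.
* **Truth** — K_true signatures (default 3), each spreading 90% of its
  probability uniformly over the sequences matching a handful of sampled
  degenerate generating patterns (context structure up to 3 bases from the
  mutation) and 10% uniformly elsewhere. The generating patterns are also
  embedded in a *planted categorization* (filled to 96 and
  conflict-resolved; resolution may occasionally replace a generating
  pattern).
* **Cohorts** — per sample, relative exposures ~ Dirichlet(0.8) and a
  Poisson burden (default mean 300 for WGS); each mutation draws a
  sequence from the exposure-mixed signature distribution (sequences whose
  context is absent from the small genome are zeroed out and the
  distribution renormalized) and is placed at a uniformly chosen genome
  position carrying that 7-mer context, on either strand. WES mutations
  are confined to the exome and the WES burden is scaled by the
  exome/genome eligible-position ratio, mimicking real sparsity.
* **Expression** — only for WES samples: coupled ("DDR-like") genes are
  softplus(coupling_strength × z-scored linear map of true exposures +
  Gaussian noise), defaults coupling 3.0 and noise SD 0.5; control genes
  are pure noise through the same link.

`fixture_small` (200 kb genome, 30 WGS + 30 WES samples, K_true = 3)
generates in a few seconds and backs every test suite. A Monte-Carlo
oracle estimates the planted held-out CCA correlation directly from fresh
draws of true exposures and expression — never touching NMF or NNLS — and
is the yardstick for the pipeline's estimated-exposure correlation.

What the generator does *not* emulate: mutational-process biology
(replication timing, strand bias), copy number, clonality, realistic
genome composition or gene-expression covariance structure. Passing
recovery tests therefore demonstrate the correctness of the machinery
under the assumed generative model, not performance on real tumors.

## Problem sizes and numerical choices

Test and demonstration runs use deliberately scaled-down settings, stated
here as package choices: GA smoke and recovery runs use S = 10, 15
ancestors and 20 generations with fitness at K-radius 1, 2 NMF restarts,
400 iterations and 5 folds; the conflict-bound check runs 100 sampled
categorizations; rank selection scans K ∈ [1, 6]. Defaults in code remain
the full-scale values above. Degenerate inputs (zero-mutation samples,
all-N genomes, zero-mass signatures, constant expression columns) raise
informative errors or warnings as documented in the module docstrings.

## Known limitations

* `select_k` is an intentionally simplified stand-in for a full
  cross-validation rank selector and is labeled as such.
* The category count is fixed at M = 96; variable-M search is out of
  scope.
* No indels, doublet substitutions or strand-specific categories; IUPAC
  three-base codes are excluded from the pattern language by design.
* Fitness evaluation is single-threaded; individuals are independent, so
  coarse parallelism is possible but not implemented.
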