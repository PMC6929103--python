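# Methods

## Ranked profiles

A differential-expression contrast is reduced to the total ordering of
its gene universe by descending log₂ fold change; rank 1 is the most
upregulated gene. Only the ordering is retained, which is what makes
profiles from different platforms commensurable and is also the method's
main assumption: any information in the *magnitudes* of the fold changes
is deliberately discarded. Ties in fold change are broken by
lexicographic gene id — a convention chosen purely for determinism
across platforms and runs. Gene ids are matched by exact, case-sensitive
string equality; identifier mapping and probe collapsing are upstream
concerns. Profiles measured on different universes must first be
intersected (`intersect_profiles`), which keeps each profile's internal
order on the shared genes and re-compacts ranks to 1..|universe|;
every pairwise statistic below requires a shared universe of size N.

## Prototype ranked list (PRL)

Replicate profiles of one biological state are merged by a greedy
closest-pair scheme: at each iteration all pairwise Spearman footrule
distances D(x,y) = Σᵢ |R(i,x) − R(i,y)| among the surviving profiles are
recomputed, the closest pair is replaced by its Borda mean-rule
aggregate (gene score = mean of its two ranks, re-ranked ascending, ties
lexicographic), and the loop repeats until one list — the PRL — remains.
Distance ties are broken by the lexicographically smallest sorted name
pair, and the merged profile is named `(left+right)`, so the full merge
trace is deterministic. Each merged profile enters later iterations with
the same weight as an original profile (no size weighting); because the
aggregate is re-ranked to integers after every merge, footrule values
remain integers throughout. The footrule is a metric on permutations
with maximum ⌊N²/2⌋ (full reversal) and mean ≈ N²/3 between independent
random orderings — useful reference points when reading a merge trace.

## RRHO maps

For cutoffs n = step, 2·step, … in list x and k likewise in list y
(top-down on both lists; trailing genes beyond the last full step get no
partial bin, keeping bins equal-sized), each pixel holds the overlap
u = |top-n of x ∩ top-k of y| and the signed −log₁₀ tail probability
under the hypergeometric distribution h(u; N, n, k) =
C(k,u)·C(N−k,n−u)/C(N,n): the over-tail P(U ≥ u) with positive sign when
u is at or above its expectation nk/N (the boundary counts as "over"),
the under-tail P(U ≤ u) with negative sign otherwise. Tails are
log-sum-exp accumulations of log-gamma pmf terms, so pixels whose
p-values underflow double precision (routine at transcriptome scale)
keep finite scores. The default step is ⌈√N⌉, scaling the pixel count
roughly linearly in N.

Two consequences of the top-down convention are worth knowing when
reading maps. First, any pixel in which one cutoff spans the whole list
has a certain overlap and scores exactly 0, so the last row/column of
every map is 0. Second, an exact reversal pins every overlap at its
minimum admissible value: no pixel is *positive*; the map maximum (0)
sits in the anti-diagonal corners and the co-upregulated corner is
strongly negative. Concordant discordance (up in one list, down in the
other) therefore appears as the *absence* of depletion toward the
anti-diagonal, not as a positive band.

Multiple-testing control across pixels is opt-in (`correct_grid` /
`--correct by`): one-sided tails are doubled (capped at 1) to two-tailed
p-values, adjusted jointly by Benjamini–Yekutieli (valid under the
strong positive/negative dependence between nested pixels), and
re-expressed as signed −log₁₀ with the original signs. Raw maps are the
default because the signed map, not a rejection set, is the primary
readout.

Per-pixel gene lists (ordered by rank in the first profile) can be
extracted and piped to an arbitrary external enrichment command
(`--enrich-cmd`); no database access is bundled.

## Enrichment-score distances

The s-length signature of profile x is its s top-ranked genes p and s
bottom-ranked genes q (s ≤ ⌊N/2⌋ keeps them disjoint; a larger requested
s is clipped and logged; the default s = 250 follows common signature
practice). The enrichment score of a gene set against profile y is the
extreme signed excursion of the unweighted Kolmogorov–Smirnov running
sum walked down y: +1/s per member, −1/(N−s) per non-member. ES = +1 iff
all members precede all non-members, −1 in the mirrored case; when the
largest positive and negative excursions tie in magnitude the positive
one is reported (determinism). Unweighted steps are used rather than
fold-change-weighted GSEA because ranks are the only retained
information.

Numerically the walk is accumulated in integers (+(N−s) per member, −s
per non-member, divided once by s(N−s)), so it returns to zero exactly
and the identities below are exact in floating point, not approximate:

- TES_{x,y} = 1 − (ES_y(p) − ES_y(q))/2 ∈ [0, 2];
- TES(x,x) = 0 and TES(x, reversal of x) = 2, exactly.

TES is asymmetric, so pairwise distance matrices symmetrize it:
D_avg(x,y) = (TES_{x,y} + TES_{y,x})/2 (the default) or
D_max(x,y) = min(TES_{x,y}, TES_{y,x}), the more permissive variant that
calls two profiles close if either direction does. Both give symmetric
matrices with zero diagonal and entries in [0, 2].

## Networks and clustering

A TES distance matrix becomes an undirected weighted graph with edge
weight 2 − D (so thresholds read as "minimum similarity"; threshold 0
yields the complete graph, and edge count is non-increasing in the
threshold). RRHO comparisons contribute a scalar edge weight as the
*maximum* signed −log₁₀ p over the grid — the strongest co-regulation
signal anywhere on the map; a center-pixel or mean summary would be
equally defensible, and the maximum was chosen as the most sensitive
single-number strength. Graphs export to GraphML (with a `weight`
attribute) or a 3-column TSV edge list; the edge list is prefixed with
one `# node:` comment line per node so isolated nodes survive a round
trip.

Profiles are grouped by affinity propagation on similarity = −distance
(scikit-learn, precomputed affinity), with damping 0.9, max_iter 1000,
and preference defaulting to the median similarity — the algorithm's
standard self-tuning choice for the number of exemplars. A fixed
`random_state` makes the tiny degeneracy-breaking jitter, and hence the
clustering, deterministic. If message passing fails to converge a
warning is raised and every profile is returned as its own singleton
cluster rather than left unlabeled. Note that exemplar-based clustering
on few points can legitimately return a single cluster when the
preference is dominated by large between-group distances; with ≥ 4–5
replicates per group the two-group simulations below are recovered
exactly.

## Synthetic fixtures

The generator emulates replicate differential-expression studies of the
same biological state: each group draws an independent base permutation
of the N genes; each replicate assigns the gene at base rank r the
latent score −r + Normal(0, (σN)²) and ranks the scores descending.
σ = 0 reproduces the base ordering exactly; σ ≈ 0.05 gives strongly
concordant replicates (within-group footrule ≈ 0.1·N²/2); large σ
decorrelates toward independent permutations (mean footrule → N²/3).
Score jitter was preferred over swap-based perturbation because a single
σ interpolates smoothly between those extremes. A companion generator
synthesizes strictly decreasing fold-change tables whose descending sort
inverts to a given profile exactly, for testing the I/O path. All
randomness flows from one explicit seed.

What the generator does *not* emulate: count/intensity noise models,
platform- or batch-specific biases, correlated gene modules, or
missingness between platforms (handled only via universe intersection).
Passing recovery tests therefore demonstrates correctness of the rank
machinery under controlled concordance, not robustness to real
measurement artifacts.

## Test problem sizes

Exhaustive checks run where enumeration is cheap: all permutation pairs
at N ≤ 6 for footrule metric structure, all 8! orderings for TES/ES
range checks, and every admissible (N, n, k, u) with N ≤ 30 against an
exact big-integer hypergeometric oracle. Simulation-based recovery tests
use N = 200–500 genes with 5 replicates per group at σ = 0.05 and fixed
seeds — sizes at which the expected effects (consensus recovery,
two-group separation) are unambiguous while the whole suite stays fast.
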