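# Methods

## Data model and curation

The unit of analysis is a taxa × samples matrix of ITS read counts with
per-sample metadata (organ ∈ {bud, twig}, site ∈ {valley, mountain}, tree).
Counts must be non-negative integers; metadata must cover every sample
exactly once. Curation keeps a taxon iff it has ≥ 10 reads in total **and**
occurs in ≥ 2 samples; both rules are applied jointly in one pass, which is
order-independent. Optional explicit min/max depth filters remove outlier
samples; no default cutoffs are imposed because depth outliers are a
property of the sequencing run, not of the method.

Rarefaction draws each sample's column from the multivariate hypergeometric
distribution at the requested depth (sampling reads without replacement),
so a sample already at the target depth is returned unchanged and the
expected retained richness follows the classical hypergeometric formula.
One function call is one seeded draw; averaging over draws is the caller's
choice (the pipeline's rarefied diversity averages 100 draws seeded
`seed + r`).

## Diversity

Shannon entropy uses natural logarithms throughout so that the identity
N2 = exp(H) holds exactly within the Hill series (N1 = richness,
N3 = inverse Simpson). Fisher's α is the root of S = α ln(1 + N/α), found
by Brent's method on a bracket grown by doubling, to relative tolerance
1e-10; it is undefined (NaN in tables) when S ≤ 1 or S ≥ N. Accumulation
curves are sample-based rarefaction estimated by averaging over seeded
random sample orderings; the endpoint equals pooled richness exactly, and
the permutation mean converges on the closed-form expectation
Σᵢ (1 − C(n−mᵢ, t)/C(n, t)).

Group differences in a diversity index use a two-sided permutation test on
the difference of group means, p = (b + 1)/(n_perm + 1). This test is
exactly level-α under exchangeability (verified by simulation in the test
suite).

## Community composition

Abundance-based ordination and PERMANOVA use Bray–Curtis dissimilarity on
square-root transformed relative abundances; occurrence-based ANOSIM uses
Jaccard distance. ANOSIM (Clarke's R with the M/4 denominator) and
PERMANOVA (pseudo-F from within/between sums of squared distances) are
computed by scikit-bio behind this package's interface; seeding is made
explicit by setting the global NumPy state for the duration of the call, so
results are bit-reproducible. NMDS minimizes Kruskal stress-1 by
alternating isotonic regression on dissimilarity ranks with configuration
updates (scikit-learn's nonmetric MDS), starting once from the classical
Torgerson solution and then from seeded random configurations; the
lowest-stress configuration wins. Because only ranks matter, any monotone
rescaling of the input leaves the stress unchanged.

A note on ANOSIM sign conventions: R as implemented measures *separation*
(R = 1 when all between-group distances exceed all within-group ones).
Reports of ANOSIM "similarity" percentages elsewhere in the literature are
not directly comparable to this R without knowing the transform used.

## Co-occurrence networks

For each organ the samples of that organ and the taxa occurring in them
form a bipartite occurrence network.

**Connectance** is realized links over possible links (equivalently the
fill of the organ's presence submatrix after dropping absent taxa).

**Nestedness temperature** T ∈ [0, 100] (0 = perfectly nested) follows the
matrix-temperature idea: pack the matrix, draw the fill isocline, and score
cells that disagree with it by their squared normalized distance from the
isocline, with the mean scaled by the 0.04145 normalizer. This
implementation is a deterministic variant:

- *Packing* sorts rows and columns by descending marginal totals. Ties are
  broken by the occurrence pattern itself (presences packed first), refined
  Weisfeiler–Lehman-style with order-invariant multiset signatures and
  iterated to a fixed point — so T is invariant to any relabeling of taxa
  or samples, and no stochastic re-packing (genetic algorithm) is involved.
- The *isocline* is the superellipse x^p + y^p = 1 whose enclosed area
  equals the observed fill; the exponent solves
  Γ(1+1/p)²/Γ(1+2/p) = fill by Brent's method on log p.
- Each unexpected cell's distance is measured along the diagonal through
  its center (direction parallel to the matrix's main diagonal), normalized
  by the diagonal's length inside the unit square; the crossing point is
  found by 60 vectorized bisection steps.

Because the packing and isocline differ in detail from other calculators
(e.g. genetic-algorithm packers), absolute T values are a documented
variant and comparisons should use this implementation consistently on both
sides of a contrast — which is what the organ permutation test does.
All-one and all-zero matrices have undefined temperature and are rejected.

**Raup–Crick scores.** For taxa A and B with observed shared-sample count
s_obs, 999 null replicates redraw, independently for every taxon, a sample
set of the taxon's observed occupancy, choosing samples without replacement
with probability proportional to per-sample richness. Then
rc = [#(s_null < s_obs) + ½#(=)]/999 ∈ [0, 1]; ties count half. The
weighted sampling uses exponential sort keys (equivalent to successive
probability-proportional-to-size draws) and is vectorized over replicates
and taxa; one replicate draws one matrix, so all pairs in a replicate share
nulls, which leaves every pairwise marginal distribution exact. Scores are
symmetric, clamped to [0, 1], and bit-reproducible given the seed.

Calibration: when focal occupancy configurations are drawn from the
richness-weighted null itself, the mean rc is 0.5 (verified to Monte-Carlo
precision in the acceptance suite). On *iid-Bernoulli* communities the mean
sits slightly below 0.5 (≈ 0.496 at 113 taxa × 16 samples): the null
assumes richness-weighted placement, and realized-richness weights always
concentrate null draws slightly more than uniform data does. The offset
shrinks with taxon count and is far smaller than the 0.49/0.5 partition
band.

**Partitioning.** Pairs with rc > 0.5 form the positive network, rc < 0.49
the negative network, and the band [0.49, 0.5] joins neither. Note this is
a median split, not a significance test: on structureless data roughly half
of all pairs land in each partition. The partitions are meaningful as
*relative* enrichment (planted exclusions score near 0, facilitations near
1) and through the index contrasts computed on them.

**Unipartite indices** (on the projection, where taxa are adjacent iff they
share ≥ 1 sample, and on both partitions, treated as unweighted graphs):

- *Assortativity*: Pearson correlation of end degrees over edges counted in
  both orientations; undefined (reported as `None`, never 0) when a
  marginal variance vanishes, e.g. regular graphs.
- *Rich-club*: φ(k) = 2E_k/(N_k(N_k−1)) over nodes with degree above the
  75th percentile of the degree sequence (percentile configurable), divided
  by the mean φ over 100 degree-preserving double-edge-swap randomizations
  (10·|E| swap attempts each). For regular degree sequences no node is
  strictly above the threshold, so the club falls back to the whole graph;
  rewiring then preserves the graph and complete graphs score exactly 1.
  Star graphs (club of one) are undefined.
- *Small-world σ* = (C/C_rand)/(L/L_rand) on the largest connected
  component, with C the mean local clustering coefficient and L the mean
  shortest-path length; null values are means over 100 Erdős–Rényi G(n, m)
  graphs matched on the component's node and edge counts and reduced to
  their own largest components the same way. Complete graphs score exactly
  1. Components with fewer than 4 nodes are rejected.

All three are computed on dense adjacency matrices (triangle counts via A³,
paths via breadth-first search) — exact, and fast enough to sit inside
permutation replicates.

**Organ comparison.** The observed difference Δ = index(twig) − index(bud)
is compared with 999 replicates that shuffle organ labels over samples
(group sizes preserved) and rebuild both organ networks from scratch,
including the Raup–Crick partitioning and any rewiring/random-graph nulls,
re-seeded per replicate from spawned child seeds. The p-value is one-tailed
on the tail matching the observed sign, p = (b + 1)/(m + 1) over the m
replicates whose indices were defined; undefined replicates are dropped and
counted (an error above 20% drops under strict mode). **Caveat:** choosing
the tail from the observed sign makes the test anti-conservative — under a
symmetric null the p-values concentrate on (0, 0.5] and the true level at
nominal 0.05 is close to 0.10. This matches the procedure as published;
users wanting a calibrated test should double the reported p.

Inside permutation replicates the internal null-model sizes default to
smaller values (199 Raup–Crick draws, 10 graph randomizations per index
evaluation) than the reporting defaults (999/100): the inner nulls multiply
with the 999 outer replicates, and the extra Monte-Carlo noise enters the
observed and null deltas symmetrically. Both knobs are configurable.

Seeding policy: every public operation takes one integer seed; internal
replicates derive child seeds via `SeedSequence.spawn` in replicate order,
so any single replicate can be reproduced in isolation and whole runs are
byte-identical across machines.

## Guilds

Trophic guilds come from a user-supplied two-column TSV (taxon → code in
{P, PSa, PSSy, Sa, SSy, U}), e.g. an export of a guild reference database;
no reference data is bundled, so no invented assignments are presented as
truth. Matching is exact name first, then the genus token, then U. Group
summaries are relative read abundances per guild and sum to 1 per group.

## Synthetic communities

The generator emulates the targeted study design: 2 sites × 2 organs ×
4 trees = 16 samples (5 trees per site gives the 20-sample design used by
the recovery studies), 113 taxa, per-sample depths log-normal
(median ≈ 30k reads) clamped to 7,766–122,310 and allocated exactly by
largest-remainder rounding with ≥ 1 read per present taxon — so counts > 0
reproduces the occurrence draw exactly and column sums match intended
depths exactly.

Occurrence: taxon t's base probability decays exponentially along the
taxon rank, p_t = 0.9·exp(−g·rank) with gradient g = 3 by default (floored
at 0.005), which produces the long occupancy tail and nested structure of
real occurrence matrices. A per-taxon Gaussian organ preference (logit
shift, mean 0.5 toward twigs, sd 1.0 by default — twigs richer than buds)
moves twig samples up and bud samples down by half the preference.
Facilitation (A, B, s) adds B where A occurs with probability s; exclusion
(A, B, s) then removes B where both occur with probability s. Exclusion is
applied after facilitation and post-hoc on realized occurrences, so
strength-1 exclusion guarantees zero co-occurrence by construction and the
ground truth is unambiguous. Read abundances are per-taxon log-normal
(σ = 1.5) with per-cell log-normal noise (σ = 0.7).

What the generator does **not** emulate: sequencing error and chimeras,
taxonomy (labels are opaque), tree-level random effects, site effects,
spatial/temporal autocorrelation, and compositional coupling beyond the
declared pairs. Passing tests therefore demonstrate correctness of the
statistics under the stated sampling model, not robustness to real
amplicon artifacts.

## Problem sizes used by the test and acceptance suites

Chosen to keep the full default run comfortable on a single CPU while
leaving Monte-Carlo error well below the asserted margins: oracle
equivalence on 55 seeded instances; Raup–Crick calibration on 500
null-drawn pair configurations (199 nulls each); type-I studies on 500
simulated datasets at 99 permutations; interaction recovery on 200
replicates per strength (199 nulls, 20 samples, occupancy ≥ 4 conditioning);
end-to-end determinism on a 50-taxon pipeline run executed twice. The
acceptance script uses the full reporting defaults (999 nulls/permutations,
100 randomizations) at study scale and finishes in a few minutes.

## Known limitations

- Nestedness temperature is a deterministic variant; absolute values are
  not exchangeable with genetic-algorithm packers, only contrasts computed
  within this implementation are.
- The 0.49/0.5 Raup–Crick partition classifies essentially every taxon pair;
  the resulting networks are dense and their indices should be read as
  descriptions of the co-occurrence structure, not as sets of significant
  interactions.
- The sign-selected one-tailed organ test is anti-conservative (see above).
- ANOSIM/PERMANOVA permute labels freely; tree identity is not used as a
  stratum, matching the single-factor usage.
- With the permutation-test defaults the smallest attainable p is
  1/(n_perm + 1); undefined-index replicates reduce the effective n_perm.
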