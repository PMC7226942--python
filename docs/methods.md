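# Methods

This note documents the models and procedures implemented in `hidpet`,
the parameters that matter, the synthetic data the tests run on, and
the numerical choices made where the design was genuinely open.

## 1. Enhancer–promoter loop processing

Inputs are BEDPE-like contact lists (column 7 = PET tag count) and a
BED4 chromatin-state segmentation. All coordinates are 0-based
half-open; two intervals overlap iff `a.start < b.end and
b.start < a.end`. Each anchor receives the labels of *all* state
segments overlapping it by ≥ 1 bp. A loop is enhancer–promoter (EP) if
some assignment of its two anchors pairs an enhancer-class label with a
promoter-class label; label classes are substring vocabularies
(defaults: `Enhancer`/`Enh` and `Promoter`/`Prom`/`TSS`) because
segmentation vocabularies differ between cell lines. The tag filter is
strict: `tags > min_tags` with `min_tags = 5`, i.e. at least six tags.
Per-antibody lists are filtered first and then merged; duplicates are
identified by exact anchor-coordinate equality (a tolerance window is a
config away but off by default), tags are summed (preserving evidence
mass), and label sets are unioned. Merging is commutative and
associative.

## 2. 1D co-localization matrix

The per-peak statistic follows the placement logic of interval
significance testing. For query peak `q` against reference set `R` on
the same chromosome, the observed distance is the genomic gap
`d = min_r max(0, r.start − q.end, q.start − r.end)` (0 on overlap,
∞ when the chromosome has no references, giving p = 1). The p-value is

    p = #{start positions s in the domain : dist([s, s+|q|), R) ≤ d} / #valid starts.

The start positions at distance ≤ d from reference `[bs, be)` form the
integer range `[bs − |q| − d, be + d]`, so the numerator is the size of
a union of integer ranges intersected with the valid starts of each
domain segment — computed analytically and equal to brute-force
enumeration *exactly* (the tie at distance = d is counted, matching a
closed inequality). The domain defaults to full chromosome extents
(`[0, max end]` per chromosome); any BED can be supplied instead.

The ordered similarity is the fraction of the query TF's peaks with
p < α (α = 0.05, raw, no multiplicity correction by design). Each TF
is the query exactly once against each other TF, so n TF sets give
n(n−1) ordered pairs (237 → 55,932). Similarities are rationals with
denominator |peaks(query)|. Directions for the hierarchy stage come
from the asymmetry: `a→b` iff `s(a→b) > s(b→a)`; exact ties carry no
direction and the pair is dropped from the directed view.

A practical constraint the synthetic generator respects: the p-value of
a *perfectly overlapping* peak is ≈ (#refs_chrom · (|q| + |r|)) /
chrom_length, so peaks must be sparse relative to the chromosome for
overlap to be significant at α = 0.05. The generator's default genome
(1 Mb chromosomes, ~30 × 200 bp peaks per TF) keeps this ratio near
0.006.

## 3. Motif occupancy and the TF lists

Sites are scored as log-odds in bits, `Σ_j log2(p'_j(x_j)/bg(x_j))`,
with matrix probabilities smoothed by a background-proportional
pseudocount (`p' = (p + 0.1·bg)/1.1`) so no cell is zero. Scores are
discretized at 1e-3 bits; the null distribution of the integer score
under the iid background is built by exact convolution across motif
positions, and the site p-value is the null tail at the site's integer
score. Because observed scores use the same integer table, the DP
p-value equals exhaustive k-mer enumeration on the discretized score
exactly; the deviation from the continuous-score enumeration is
bounded by width × 1e-3 bits. Both strands are scanned (reverse
complement of the PWM on the forward sequence); windows containing
ambiguity codes are skipped. The site threshold defaults to 1e-10 —
note this is only attainable for motifs with 4^−width ≤ 1e-10, i.e.
width ≥ 17; the synthetic generator therefore plants 18-mers.

Enhancer-side presence of a TF (list A) is ≥ 1 significant site in any
enhancer anchor. Promoter-side presence (list B) is rank enrichment:
promoter anchors are ordered by the TF's best site score (ties broken
by anchor id), the positives are the anchors carrying a significant
site, and the statistic is the minimal hypergeometric tail
P(X ≥ |positives ∩ top-k|) over all cutoffs k; the TF is present when
this p < 0.05. Two degeneracies are handled explicitly: when *every*
promoter anchor carries a site the tail is 1 by construction and
presence falls back to the occurrence call; and with few anchors the
smallest attainable tail is 1/C(N, K), so enrichment-based presence is
only meaningful with enough anchors (the generator plants ≥ 10 EP
loops). A `per_promoter=True` flag replaces the enrichment call with
the plain occurrence call. The final TF list is A ∩ B.

The site threshold can be tuned across cell lines on a grid
1e-7..1e-13 (×10 steps): for each grid point the mean pairwise Jaccard
similarity of the per-cell final lists is computed, and the chosen
threshold is the interior grid point with the largest |discrete second
difference| (the inflection of the agreement curve); a flat curve
falls back to 1e-10.

## 4. PPI intersection and similarity network fusion

The 3D matrix is the binary adjacency over the final TF list with an
edge iff the pair is in STRING with combined score strictly > 400 and
in BioGRID with experimental evidence (evidence strings matched by the
configurable substring list `("experimental",)`).

Fusion restricts both matrices to their shared TFs. The asymmetric 1D
matrix is symmetrized by the arithmetic mean; both affinities receive
an off-diagonal floor ε = 1e-3 (so isolated rows remain normalizable);
each becomes a full transition kernel (off-diagonal mass ½ split
proportionally, diagonal ½) and a row-stochastic K-nearest-neighbour
local kernel (K defaults to max(2, ⌊n/10⌋)). Cross-diffusion updates
run in parallel for t = 20 rounds: `P1 ← S1·P2·S1ᵀ`, `P2 ← S2·P1·S2ᵀ`,
each re-imposed to the half-diagonal row-stochastic form and
re-symmetrized — without that renormalization the diffusion washes out
to a near-constant matrix. The fused matrix is the average of the two
kernels, symmetric and non-negative at every iteration.

Properties worth knowing: self-fusion of a *module-structured*
affinity (two-valued: high in-module, low across) preserves the entry
ranking exactly; for arbitrary continuous affinities cross-diffusion
is not entrywise monotone and ranking is not preserved — the pipeline
feeds it module-structured similarity, which is the regime that
matters. K-NN tie-breaking is index-based, so exact permutation
equivariance holds only for tie-free affinities.

Binarization keeps undirected edges with fused weight strictly above
the mean off-diagonal weight (a quantile rule is available); an
all-equal weight matrix yields no edges, with a warning. The directed
overlay is the 1D-derived directions restricted to kept edges; TFs
without any incident directed pair simply do not appear in the
directed view.

## 5. Hierarchy inference

A level assignment maps each TF of the directed overlay to a level in
{1..L}, level 1 on top. The raw hierarchy score is the mean edge sign,
`HS = (1/|E|) Σ_(u→v) sgn(level(v) − level(u))` ∈ [−1, 1]; reversing
the level order negates it. The corrected score is the z-score of HS
against the null of random node relabelings that preserve the level
sizes.

The null moments are computed in closed form. The null mean is exactly
0 (the joint level distribution of an ordered node pair is
exchangeable, and `n_a n_b sgn(b−a)` sums antisymmetrically). The
variance decomposes over edge pairs by shared nodes:
`Var(HS) = (1/m²)[m·q2 + 2(−A·q2 + C_th·T_tail + C_ch·T_chain +
C_dis·D4)]`, where q2 = P(two distinct nodes on different levels),
T_tail/T_chain/D4 are sign-product expectations over level
triples/quadruples (O(L⁴) terms, L ≤ 8), and A, C_th, C_ch, C_dis
count antiparallel, shared-endpoint, chained and disjoint edge pairs
(graph constants). A Monte-Carlo estimator over R permutations is kept
as an alternative and agrees with the closed form to ~3 decimals at
R = 3·10⁵. The closed form matters: the z-score gaps separating the
true level count from its refinements are of the same order as the
Monte-Carlo noise at R = 1000, so a sampled null makes the level
selection unstable.

Simulated annealing (restarts = 10, steps = 200·n, T0 = 1, geometric
cooling 0.995, all randomness seeded) relocates one node per move,
keeps every level non-empty, and applies Metropolis acceptance on the
corrected-score change; the raw-score change is computed incrementally
from the moved node's incident edges and the null sd is cached by
level-size vector. L is searched over 2..8; the L with the highest
best corrected score wins (smallest L on ties). Per-node level
probabilities are the frequencies of each node's level across the
winning L's restart optima; the reported level is the mode. Level-link
ratios divide observed undirected links between (within) levels by
n_i·n_j (n_i(n_i−1)/2); levels with < 2 nodes are flagged and report
a within ratio of 0.

## 6. Communities, cliques, dynamics, coherence

Cohesiveness is `f(V) = w_in/(w_in + w_bound + p|V|)` with penalty
p = 2. Growth starts from unused seeds in descending weighted degree
and repeatedly applies the best single add/remove step until no step
increases f; every returned community is locally optimal by
construction (the two-triangle fixture returns exactly the two
triangles, which are also the brute-force co-optima among subsets of
size ≤ 4 — the *global* optimum over all subsets is the whole graph,
which the local dynamics deliberately do not reach). Grown sets with
overlap score |A∩B|²/(|A||B|) ≥ 0.8 are merged transitively; final
sets need ≥ 3 members and edge density ≥ 0.5. Nodes may appear in
several communities.

Maximal cliques come from Bron–Kerbosch with pivoting
(`networkx.find_cliques`), filtered to sizes 3–10; tests verify
equality with all-subsets enumeration on graphs ≤ 12 nodes. Cliques
are identical across cell lines iff their TF-name sets are equal;
the Venn partition assigns each distinct member set to the set of
cells containing it. A clique regulates gene g iff some EP loop's
promoter anchor overlaps g's TSS and *every* clique TF has a motif
occurrence in that loop's promoter or enhancer anchor — antitone in
clique size by construction. Shared-clique patterns: identical member
sets with regulated-gene Jaccard ≥ 0.9 are "same clique, same genes";
identical members below that are "same clique, different genes";
different member sets sharing ≥ 3 TFs are "partial TF sharing".

Expression coherence compares Spearman ρ (average-rank ties) of every
TF pair co-occurring in ≥ 1 clique against every pair never
co-occurring, over the union of clique members; pairs with a constant
expression vector are dropped with a warning. The one-sided Wilcoxon
rank-sum (within > between) is exact for combined n ≤ 20 and a
tie-corrected normal approximation otherwise (`scipy.stats.
mannwhitneyu`); tests verify the exact path against full enumeration.

## 7. Clique–gene biclustering

The binary clique×gene matrix (all-zero rows/columns retained) is
fitted with a sparse multiplicative factor model `X ≈ ΛZ`, F = 10
factors, up to 10,000 sweeps. This preserves the model class of
variational Laplace-prior factor analysis while keeping the fit exact
and deterministic: SVD initialization (sign-fixed), then alternating
exact rank-one minimizations with soft-threshold shrinkage
(sparseness 0.01) on loadings and factors. Each sweep is an exact
blockwise minimization of the penalized objective
`½‖X − ΛZ‖² + α(‖Λ‖₁ + ‖Z‖₁)`, which is therefore non-increasing and
asserted per sweep; the *plain* reconstruction error is not the
monotone quantity — from the least-squares-optimal SVD start,
shrinkage trades a little reconstruction for sparsity. Convergence is
declared when the relative reconstruction change drops below 1e-6.

The matrix is fitted **uncentered** by default: factors then align
with blocks of 1s (the biclusters). Column centering (available via
`center=True`) turns each block into a block-vs-complement contrast,
and whenever a block covers ≥ half the rows the complement carries the
larger |loading|, breaking support recovery. Memberships per factor
are |loading| at or above the 0.9 quantile, capped at half the
factor's peak magnitude (so supports wider than 10% of a dimension,
where the quantile falls among near-tied member values, are kept
intact); exact zeros are never members. The superclique–gene-group
graph weights edge (S_i, G_j) by the number of regulated (clique,
gene) pairs between the sets; zero-weight edges and empty groups are
dropped. Equal-area disjoint blocks make the truncated SVD degenerate
(equal singular values), so planted fixtures use distinct block areas.

## 8. Synthetic data: what it emulates, and what it does not

`FixtureConfig` defaults define the desk-scale study conditions: 2
chromosomes × 1 Mb, 12 TFs in planted levels [4,4,4], 3 cross-level
cliques of 3 embedded in 2 communities, 40 loops (80% EP), 18-bp
implanted consensus motifs, ~30 peaks/TF with 90% of a clique's peak
midpoints shared within ±20 bp jitter, ≥ 95% downward influence
edges (2% flipped), expression as one uniform latent profile per
clique plus a per-TF offset and Gaussian noise (sd 0.1), five
replicates per cell line mirroring typical RNA-Seq replication, and
two noise-free planted biclusters of distinct areas. Peak counts grow
slightly with planted level so the 1D asymmetry points downward. Two
cell lines are derived by dropping different residue classes of the
loop list, giving mostly-shared and some cell-specific loops. Fixed
seed ⇒ byte-identical bundle files.

Deliberately *not* emulated: read-level noise and peak-calling
artifacts; degenerate (information-weighted) motifs — consensi are
implanted exactly so scan recovery is deterministic; realistic PPI
false-positive structure; expression dynamic range and
mean–variance coupling; inter-chromosomal loops. Passing tests
demonstrate that each stage recovers what it is designed to recover
under its stated model, not that the thresholds are optimal for any
particular real cell line.

## 9. Known limitations

- The placement p-value treats reference peaks independently of local
  chromatin context; there is no FDR control over peaks (by design,
  α = 0.05 raw).
- The corrected hierarchy score cannot distinguish a level count from
  refinements *of the same ordering* by the raw score alone; the
  selection rests entirely on the null variance, which is why the
  closed-form null is the default.
- Promoter-side rank enrichment is uninformative when nearly all
  anchors are bound or when very few anchors exist (minimal attainable
  tail 1/C(N, K)).
- SNF free parameters (K, t, ε) are conventional defaults; they are
  logged in the run manifest but not tuned.
- Clique identity across cells is exact set equality; near-identical
  cliques land in the "partial TF sharing" pattern instead.
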