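# Methods

This note documents the models and algorithms implemented in `ibdnet`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data validation does and does not
establish.

## 1. The IBD network model

The object of study is a weighted undirected graph whose vertices are
genotyped individuals and whose edges summarize pairwise identity by
descent. The premise is quantitative: for two individuals whose only
connection is one shared common ancestor `g_a` and `g_b` meioses up, the
probability that a given genomic position is IBD is

```
P = (1/2)^(g_a + g_b - 1)
```

(the first meiosis on each side necessarily transmits one of the
ancestor's two allele copies; each further meiosis retains it with
probability 1/2; the two sides must have picked the same copy). At four
generations on both sides this is 1/128 ≈ 0.78% — recent ancestry
leaves detectable segments, but the signal is sparse, which is why very
large cohorts and a network representation are needed. The closed form
is checked in the test suite by a 10⁵-replicate single-locus
gene-dropping Monte Carlo (`annotate.kinship_gene_drop_mc`).

### Edge weights

A pair's total detected IBD `t` (cM) maps to a weight

```
w(t) = 0                                   if t <= 12 cM
w(t) = BetaCDF(t / s; alpha=2, beta=200)   otherwise
```

interpreted as the proportion of IBD at that level of sharing that is
attributable to "recent" relationships — common ancestors at most 8
meioses (≈ 4 generations) away. The shape defaults (α = 2, β = 200) are
the production values; `network.calibrate_weight_curve` refits them by
weighted least squares on gene-dropped simulations in which every pair's
true meiosis count is known (pairs are binned by total IBD; each bin's
ordinate is the fraction of its IBD mass contributed by ≤ 8-meiosis
pairs). Two thresholds structure the graph:

* **12 cM inclusion** — below this, sharing almost never reflects the
  target relationships (w(12 cM) ≈ 0.05 under the default scale), so no
  edge is stored;
* **72 cM family exclusion** — above this, pairs are close relatives;
  these edges are removed before clustering *and* spectral analysis so
  extended families do not masquerade as populations. (The removal is
  stated for the clustering stage in the source method; we apply it to
  both stages for consistency, since family-driven eigenvectors would
  otherwise dominate the embedding.)

The Beta argument's scale `s` is not pinned down by the source method;
we default to one diploid genome length (2 × total map cM, i.e. 7,120 cM
for the human autosomes), under which the CDF at the 12 cM threshold is
a few percent, consistent with the stated rarity of familial signal at
the threshold. `s` is a config field and the calibration can refit the
shape at any scale.

## 2. Segment detection

`ibdseg.detect_ibd` reimplements the GERMLINE seed-and-extend scheme on
phased haplotypes: each chromosome is cut into consecutive
non-overlapping words of `bits = 96` SNPs; per word, haplotypes are
bucketed by their packed allele bytes (an exact encoding — seeding
admits no collisions); every cross-sample haplotype pair sharing a word
is extended SNP-by-SNP in both directions with zero mismatch tolerance
(`err_hom = err_het = 0`); per sample pair, calls from the four
haplotype pairings are union-merged into maximal SNP intervals; merged
intervals of genetic length ≥ `min_m = 5` cM are reported.

Consequences worth knowing:

* shared runs containing no complete word are undetectable by
  construction (the sensitivity floor of fixed word boundaries);
* with zero mismatch tolerance the detector is exactly equivalent, on
  error-free input, to a brute-force maximal-exact-match scan restricted
  to runs containing a full word — the test suite asserts identity
  against such an oracle on a 50-sample, 5,000-SNP cohort;
* the union-merge across haplotype pairings is our resolution of an
  under-specified corner (how per-pairing extensions combine); it can
  merge adjacent segments inherited through different ancestors.

A segment's genetic coordinates are `[pos(first SNP), pos(last SNP))`;
genetic length is the positional difference. Pair totals
(`aggregate_pairs`) keep pairs with total strictly greater than 5 cM.

## 3. Clustering

Partitions maximize weighted Newman–Girvan modularity
`Q = Σ_c (e_c/m − (a_c/2m)²)`. The optimizer is the seeded multi-level
(Louvain) heuristic (via networkx, as the original analysis used the
igraph implementation); only its final flat partition is used, never its
internal merge hierarchy. `recursive_cluster` applies the algorithm to
the largest connected component, then re-applies it to the induced
subgraph of every cluster with at least `min_cluster_size` members
(default 100 at desk scale), to a default depth of 2 levels (3
optional). Stopping rules for such recursions are not well established;
depth and minimum size are config, not doctrine. Per-cluster densities
W_in (mean weight of within-cluster edges) and W_out (mean weight of
member/non-member edges) are recorded at every level; a cluster with no
qualifying edges gets density 0 plus a flag.

Determinism: the Louvain seed is fixed per pipeline run (fanned out from
the global seed), and output labels are canonicalized by decreasing
cluster size with smallest-member tie-break, so reruns are
reproducible and vertex relabelling permutes labels only.

## 4. Spectral embedding and stable subsets

The embedding is the top-`m` eigendecomposition of
`L = D^{-1/2} W D^{-1/2}` with unit self-weights `W(i,i) = 1` and
degrees that include the self-weight. Note the convention: this matrix
is the normalized adjacency (the random-walk smoother), written the way
the Laplacian-eigenmaps literature writes it; its *top* eigenvectors
carry the weakly-connected block structure, its spectrum lies in
[−1, 1], and the leading eigenvalue of a connected graph is exactly 1
with eigenvector ∝ √d. It relates to the usual normalized Laplacian by
`L_sym = I − L`. Production default m = 40; the desk-scale default is
m = 10 (small synthetic networks have few informative directions). The
eigengap heuristic is deliberately not used for choosing m — these
networks do not have well-pronounced modules at the top level.

Numerics: graphs up to 500 vertices use a dense `eigh`; larger graphs a
Lanczos solver (`eigsh`, `which="LA"`) started from the exact leading
eigenvector √d for reproducibility. Signs follow the convention that
each eigenvector's largest-magnitude entry is positive. The test suite
requires eigen-residuals ≤ 1e−6 and agreement with a dense
decomposition to 1e−8 on 200-vertex graphs.

**Stable subsets.** The original analysis extracted, by manual
curation, clusters whose members project away from the origin in some
2-d eigenvector view; the tabulated per-subset rotations and half-plane
rules were chosen by hand. Our extraction is an automated stand-in: for
each eigenvector pair (j, k) with 1 ≤ j < k < m (the trivial leading
vector is skipped) and each cluster, rotate the view so the cluster
centroid points along +Y1 (refined over ±15° in 1° steps), take the
half-plane Y1 ≥ τ with τ chosen to maximize Youden's J = TPR − FPR,
and accept when τ > 0, the false-positive rate (selected non-members /
selected) is ≤ 5% and recall is ≥ 90%; the best accepted view per
cluster is kept. Selected non-members are reported but excluded from
the subset. The rule is invariant to global sign flips, reduces to
connected components in the exact-disconnection limit, and accepts
nothing on homogeneous random graphs at the default caps — but it is
validated on planted structure only and is not a reimplementation of
the original curation.

**Second pass.** Removing stable-subset members and re-embedding the
residual (largest component, logged if disconnection occurs) exposes
blocks masked by dominant structure in the first pass.

**Out-of-sample projection.** A new sample with cross-network weights
`w(new, j)` and degree `d_new = 1 + Σ_j w(new, j)` (unit self-weight
included) gets coordinates from the Nyström-style augmented eigen-row

```
c_k (λ_k − 1/d_new) = Σ_j w(new, j) v_k(j) / sqrt(d_new d_j)
```

The self-loop term on the left makes the extension exact for network
vertices projected as if new (the familiar `(1/λ) Σ ...` form drops it
and is only approximate); coordinates with |λ_k − 1/d_new| below 1e−8
are zeroed and flagged unstable. Samples with no qualifying IBD map to
the origin.

## 5. Annotation

* **Birth-location grids.** An annotation is one (genotyped sample,
  ancestor) link; within a generation window (generation 0 = the
  genotyped individual) each ancestor's birth location is snapped to the
  nearest 0.5° grid point (round-half-to-even on the doubled
  coordinate, i.e. standard nearest-multiple rounding). Each point
  stores member and non-member annotation counts and the mean lat/lon
  of its annotations (used as the plot position). Counting annotations
  rather than distinct ancestors is a choice; an ancestor shared by a
  member and a non-member contributes to both sides.
* **Odds ratios.** `OR = (a/(A−a)) / (c/(C−c))` per grid point, with a
  Haldane–Anscombe +0.5 applied to all cells when any is zero (needed on
  sparse grids; the source method is silent here). Points with fewer
  than 10 member annotations are excluded from the plotted set but keep
  their OR.
* **Kernel PCA.** Region-level totals `t(i,j)` accumulate the total IBD
  of pairs sharing > 12 cM; `K(i,j) = t(i,j)/√(d(i)d(j))` removes
  variation in overall regional IBD. K is double-centered (standard for
  kernel PCA; an uncentered variant is available by flag) and
  eigendecomposed; scores are eigenvector × √eigenvalue. K is not
  guaranteed positive semidefinite; negative-eigenvalue directions are
  clipped to zero score. On a 10-deme one-dimensional stepping-stone
  simulation, PC1 orders the demes along the habitat (|Spearman ρ| ≥
  0.9 in the test suite) — the planted-geometry analogue of PC1
  tracking geography in real data.
* **F_ST.** Hudson's estimator with per-SNP numerator
  `(p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)` and denominator
  `p1(1−p2) + p2(1−p1)`, where n counts alleles; the estimate is the
  ratio of summed numerators to summed denominators (ratio of averages),
  which adjusts for sample-size differences. SNPs with call rate < 95%
  in either group are dropped; monomorphic-everywhere input is flagged
  undefined. Small negative estimates are legitimate estimator noise.
  Weir–Cockerham is intentionally not implemented; the ratio-of-averages
  Hudson form is the estimator of record here.

## 6. The synthetic-data generator

`simpop` emulates the features of real cohort data this pipeline
actually consumes:

* **Pedigrees** — discrete non-overlapping generations; per deme and
  generation a fixed census (`deme_size`); random monogamous mate pairs
  within a deme, cross-deme with probability `migration_rate` (uniform
  partner deme under "island", adjacent deme under "line" for
  stepping-stone geography); children assigned to pairs uniformly at
  random. Birth year = 2000 − 25·generation; birth location = deme
  centroid + Gaussian jitter (0.1° default).
* **Gene dropping** — founders carry uniquely labelled haplotypes;
  every transmission draws crossovers as a Poisson process at 1 per 100
  cM (Haldane, no interference) with a fair-coin starting haplotype.
  Ground-truth IBD segments are maximal intervals where any of the four
  haplotype pairings carries the same founder label, union-merged per
  pair. The default desk map is 10 chromosomes × 150 cM; a 22 × 160 cM
  option approximates autosome scale.
* **Genotypes** — ancestral frequencies Uniform(0.05, 0.95); deme
  frequencies Balding–Nichols `Beta(p(1−F)/F, (1−p)(1−F)/F)` (F = 0
  short-circuits to p); founder haplotypes draw alleles from their
  deme's frequencies; descendants copy alleles through the mosaic, so
  IBD segments are identical by state with zero genotyping error.

What it does **not** emulate — and therefore what passing tests do not
show about real data: genotyping and phasing errors (the detector is
exercised at its error-free optimum), SNP ascertainment and array
versions, overlapping generations, variable family sizes and
non-monogamy, sex chromosomes, mutation, and real human geography.
Planted-structure recovery (ARI ≥ 0.9 at migration 0.01 over five
200-member demes; exact recovery in the zero-migration limit) is a
correctness check of the machinery, not a statement about power on real
cohorts.

## 7. Problem sizes and runtimes

The shipped test and validation runs are sized for a single CPU:
five demes × 200 individuals × 6 generations (7,000 pedigree members,
1,000 genotyped) for clustering recovery; 50 samples × 5,000 SNPs for
detector/oracle equivalence; 200-vertex graphs for spectral oracles;
10,000 SNPs × 50+50 samples for F_ST calibration (the Balding–Nichols
check uses unrelated individuals drawn directly from deme frequencies,
since pedigree relatedness would only add variance). The full suite
runs in under a minute; `scripts/acceptance.py` in seconds. All
randomness flows from explicit seeds; the pipeline fans one global seed
into per-stage child seeds via `numpy.random.SeedSequence`, and reruns
reproduce artifacts byte-for-byte (checksummed in the manifest).

## 8. Known limitations

* The stable-subset extractor is an automated proxy for a manual
  procedure; its acceptance caps (FP ≤ 5%, recall ≥ 90%, minimum size)
  are config and were chosen to be conservative on null graphs.
* The weight function's argument scale is a package choice (one diploid
  genome), not an inherited constant; calibration refits shape but the
  scale convention affects the absolute weight values.
* The calibration's relationship-depth mix is whatever pedigree the
  user simulates; no canonical mix is bundled.
* `min_cluster_size` interacts with deme size: clusters smaller than
  the threshold are never subdivided, and at desk scale the default
  (100) stops most second-level splits — deliberate, since the planted
  demes are the finest real structure in the simulations.
* The detector has no mismatch budget (by design, matching the
  zero-error parameterization); on data with genotyping error it will
  fragment segments.
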