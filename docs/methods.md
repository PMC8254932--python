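# Methods

## Scope and data model

`tadclique` analyzes intra-chromosomal, fixed-resolution raw Hi-C
contact counts (HiC-Pro triplet `.matrix` + bin `.bed` dialect). All
coordinates are 0-based half-open internally; HiC-Pro's 1-based bin ids
are converted at the I/O boundary. Contact maps are stored
upper-triangular and queried symmetrically. A chromosome's TAD
segmentation always tiles it completely: intervals between called
domains are kept as explicit gap segments (`gap_` name prefix in BED
output) so that every base pair, bin and gene has a well-defined home.
Inter-chromosomal contacts, ICE normalization and binary `.hic`/`.cool`
formats are out of scope.

## TAD calling

The caller maximizes the summed quality of non-overlapping domains.
For a domain over bins `[k, l]` with internal contact sum `s(k, l)`
(upper triangle, diagonal included) and length `d = l − k + 1`:

    q_gamma(k, l) = s(k, l) / d**gamma − mu_gamma(d)

where `mu_gamma(d)` is the mean of `s/d**gamma` over **all** length-`d`
windows of the chromosome (a global per-length mean; a running local
mean is a known alternative and would change scores near intensity
gradients). The resolution parameter γ (default **1.2**, the common
choice for 50-kb human maps) trades domain size against density:
larger γ favors smaller domains.

The dynamic program `OPT(l) = max(OPT(l−1), max_k OPT(k−1) + q(k, l))`
considers only domains with positive quality, at least
`min_domain_bins` = 4 bins (200 kb at 50-kb resolution, the smallest
domain size the analysis trusts) and at most 2 Mb (bounding cost and
matching observed TAD scales). Ties break toward the shorter domain so
output is deterministic. Only the single optimal segmentation is
produced (no near-optimal ensemble). Window sums use 2-D prefix sums,
so calling is O(n · cap) after an O(n²) precompute.

On synthetic maps the optimizer frequently subdivides a planted domain
into two or three positive-quality fragments while placing boundaries
exactly (boundary recall 1.0 at default conditions). This is a property
of the γ-scaled objective under Poisson counts, observed across decay
exponents 0.7–1.3 and intra-TAD boosts 2–5, not a calibration artifact;
recovery scoring therefore projects called fragments onto planted
domains by midpoint containment (see "Evaluation against ground
truth").

## Interaction testing

Eligible pairs are linearly non-contiguous TADs: at least one other
tested segment must lie between them (gap segments are excluded from
testing by default — `include_gaps` reverses that — and do **not**
break the adjacency of the domains flanking them). Pair distance is
midpoint separation.

Distance decay is modeled by log-spaced distance strata (default 30).
Each stratum carries two statistics over its pairs:

* `E_d` — the raw mean observed pair count, used for the
  **fold-enrichment filter** `x / E_d ≥ 5`, i.e. enrichment of observed
  over expected contacts *based on genomic distance alone*;
* `omega_d` — the mean of `x·N/(n_a·n_b)`, a size-normalized
  enrichment, used as the odds parameter of the significance test.

Empty strata inherit the nearest non-empty stratum's values.

Significance of an observed count `x` for a pair `(a, b)` comes from
the upper tail of Fisher's non-central hypergeometric distribution with
parameters `(n_a, n_b, N)` — each TAD's total contacts and the
chromosome total (full-matrix sums, so Σ n_a = N) — and odds
`ω = omega_d`, which centers the null on the pair's distance- and
size-aware expectation `omega_d · n_a · n_b / N`. The pmf is normalized
explicitly over its support in log space (log-sum-exp); direct products
overflow at realistic `N`. Using the raw `E_d` as the null center
instead makes the test anti-conservative (measured null type-I
fraction ≈ 0.09 at p < 0.05 versus ≈ 0.045 with the size-normalized
odds) because all pairs of a stratum would share one expectation
regardless of their contact totals.

Benjamini–Hochberg correction is pooled over all tested pairs of all
chromosomes supplied (FDR < 1% by default); a pair is significant iff
`q < fdr` **and** it passes the five-fold distance filter. TADs with
zero contacts are skipped and logged.

## Clique statistics

Significant pairs define a simple undirected graph over TAD ids (TADs
without significant partners remain as isolated nodes). Maximal cliques
are enumerated with the Bron–Kerbosch algorithm with pivoting
(`networkx.find_cliques`), sorted lexicographically for determinism,
and cross-checked in the test suite against exhaustive subset
enumeration. Per TAD: degree; maximal clique size `k` (largest maximal
clique containing it, 1 for isolated nodes); ratio `k/(degree+1)` (1
exactly when the TAD's closed neighborhood is a clique — trivially so
for singletons); category singleton / binary / clique_3 … clique_7 /
clique_8plus. Because adjacent-TAD pairs are never tested, clique
membership automatically honors linear non-contiguity.

## Characterization

* **Aggregate heatmaps** — each TAD's intra-TAD bin matrix is resized
  to 25×25 by nearest-neighbor index mapping (target cell `(r, c)`
  reads source cell `(⌊r·m/25⌋, ⌊c·m/25⌋)`), then averaged cell-wise
  within a category. Nearest-neighbor preserves constants and raw count
  scale.
* **CTCF convergence** — a TAD is convergent iff the highest-score
  motif in the `window_bp` of sequence just inside its 5′ boundary is
  forward-strand **and** the highest-score motif just inside its 3′
  boundary is reverse-strand. The window is inward-facing (default one
  bin, 50 kb): loop-anchor motifs reside inside their domain, and a
  symmetric window would capture the neighboring domain's
  opposite-orientation anchor at every shared boundary, flipping about
  half of all calls. The highest-score tie-break favors the strongest
  binding evidence and is deterministic. Per-category convergent
  percentages are tested against the genome-wide fraction `p0` with a
  two-sided exact binomial test (tail doubling, capped at 1); category
  percentages weighted by category sizes reproduce `p0` exactly.
* **Repeat / annotation coverage** — per-TAD covered fraction =
  |union(annotation) ∩ TAD| / |TAD| in exact integer bp; overlapping
  annotation intervals are merged first.
* **Expression** — genes are assigned to the segment containing their
  TSS (a gene spanning a boundary belongs to exactly one TAD; genes in
  gap segments are dropped); clique (k ≥ 3) vs non-clique expression is
  compared with a two-sided two-sample KS test.
* **Subcompartments** — per TAD, the overlapping annotated segment
  maximizing the base-pair Jaccard index gives the TAD's label; a
  per-label-union variant is available (`per_label_union`) since both
  readings are defensible. B-compartment-restricted reruns are the same
  operations applied to the TAD subset whose best label is B1–B4.

## Cross-cell-type clustering

A clique's footprint is the merged bp union of its member TADs, making
comparisons robust to differing boundary calls between cell types (a
TAD-id Jaccard would be meaningless across cell types). For each
reference clique the best-matching clique per other cell type is found
by maximal footprint Jaccard; the resulting matrix is clustered with
k-means (k = 8, 10 restarts, seeded). Cluster labels are canonicalized
in descending order of cluster mean JI, so cluster 1 is always the most
conserved set.

## Synthetic data generator

Counts for bin pair `(i, j)` are Poisson with mean

    mu_ij = L · (1+|i−j|)**(−alpha) · (1 + beta·[same TAD])
              · (1 + gamma_c·[planted clique edge])

Defaults (the package's canonical study conditions): 40 Mb chromosome,
50 kb bins, decay exponent α = 1 (the fractal-globule regime typical of
Hi-C at these scales), base intensity L = 20 (raw-count scale giving
TAD-pair totals of tens to hundreds), intra-TAD boost β = 3, TAD sizes
drawn uniformly on 0.2–1 Mb (sequentially, rounded to whole bins; a
final fragment under 200 kb becomes a gap), and planted cliques of
sizes 3/5/8 with edge boost γ_c = 8 between pairwise non-adjacent
member TADs. γ_c = 8 is calibrated to the five-fold significance
filter: a planted pair's expected enrichment (1 + γ_c) must clear it
with margin. Poisson (not negative-binomial) counts are the simplest
model consistent with raw Hi-C; overdispersion is a possible extension.

Companion annotations: convergent CTCF motif pairs placed just inside
TAD boundaries with probability 0.6 (non-clique) vs 0.1 (clique TADs),
plus uniform random-strand decoys at 1 per 500 kb that force the
convergence scorer to handle off-boundary motifs; LINE tiles covering
40% of clique vs 25% of other TADs with complementary SINE; per-gene
log2 expression Normal(5, 2) shifted down by 1 inside clique TADs
(about one gene per 100 kb); subcompartment labels with B2/B3 drawn at
probability 0.8 over clique footprints.

What the generator does **not** emulate: read-level noise and mapping
artifacts, copy-number and ICE-normalization effects, inter-chromosomal
contacts, overdispersion, replicate structure, hierarchical
(nested) TADs, and correlated annotation tracks. Passing tests
therefore demonstrate the correctness and calibration of the
algorithms under the stated generative model, not performance on any
particular real dataset.

## Evaluation against ground truth

Because the caller may segment finer than the planted domains, each
called TAD is mapped to the planted segment containing its midpoint.
Edge precision = fraction of significant called pairs whose mapped pair
is a planted clique edge; edge recall = fraction of planted edges hit
by at least one significant pair; the per-TAD "k reaches planted clique
size" property is evaluated on the projected graph. At default
conditions (seed 1): precision 1.0, recall 1.0, boundary recall 1.0
within ±1 bin, and null type-I fraction ≈ 0.045 at p < 0.05.

## Numerical and degenerate-input choices

* NCHG p-values: explicit log-space normalization; `x` outside the
  support or ω ≤ 0 are errors; ω is clamped below at 1e-12 in the
  pipeline.
* DP ties break toward shorter domains (epsilon 1e-12); maps shorter
  than the minimum domain return a single gap segment with a warning.
* Aggregation requires the segmentation to tile the map's chromosome;
  a bin midpoint outside every segment is an error.
* Empty inputs: empty triplet files parse to zero-triplet maps; empty
  BH input returns empty output; an empty category or a class with
  fewer than two genes is an error.
* k-means requires at least k rows; labels are deterministic given the
  seed.

## Problem sizes

Tests and the acceptance script run the full pipeline on the default
40 Mb single-chromosome fixture (800 bins, ≈ 65 planted TADs, ≈ 130
called domains, ≈ 8 500 tested pairs) and on 10–20 Mb variants for
replicated checks; these sizes give stable statistics for every
property tested while keeping each suite run to a few minutes on one
core. Real multi-chromosome datasets are processed per chromosome with
pooled FDR, so cost scales linearly in chromosome count.
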