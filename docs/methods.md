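# Methods

This note documents the statistical procedures, their assumptions, the
generator that stands in for field data, and the numerical choices that a
maintainer would otherwise have to reverse-engineer.

## Study design and data model

The target design is a grid-structured survey: *k* rectangular plots (one
per succession stage), each divided into an *r* × *c* lattice of quadrats,
one pooled soil sample per quadrat. Default: 4 plots × 5 × 5 quadrats =
100 samples, two marker domains (bacteria-like and fungi-like) profiled on
the same samples. An `OtuTable` is a samples × OTUs matrix of non-negative
integer read counts; every sample must have positive depth (the design has
no empty quadrats, so an all-zero row is treated as a data error, not
silently dropped). Quadrat indices are 0-based with (0, 0) at a plot's
south-west corner; the convention is arbitrary but fixed, because the
torus-translation null depends on cell adjacency, and it is recorded in
output headers.

## Torus-translation habitat association

*Statistic.* T_h = mean over cells labelled *h* of (OTU count / sample
depth). Depth normalisation removes sequencing-depth differences between
quadrats, which would otherwise masquerade as habitat signal. Raw-count and
presence statistics were considered and rejected as defaults: raw counts
confound depth, presence throws away abundance information at these depths
(nearly every OTU is present everywhere).

*Null.* The composite habitat map (plots tiled into one lattice, default
2×2 → 10×10) is translated to every (dx, dy) offset on the torus, for each
of the four map symmetries (identity, 180° rotation, mirror, mirrored
rotation): 4·W·H maps, 399 with the identity excluded (the default).
Coinciding maps produced by a symmetric mosaic are *not* deduplicated, so
the null size is always exactly 4·W·H − 1. With 399 null values the
achievable two-tailed resolution is ~0.005 per tail, ample for α = 0.05;
empirical quantiles are used without interpolation.

*Decision rule.* The observed statistic's mid-rank among the null values
(ties count one half, detected with relative tolerance 1e-9 — identical
cell values summed in different orders differ by ulps) is compared with
(1 − α/2)·N and (α/2)·N. A constant OTU ties every null value, sits at
rank N/2, and is never flagged. Under the neutral model the identity map is
exchangeable with the other 399, so each tail's rejection probability is
exactly 10/400 = 0.025 at α = 0.05.

*Composite-layout caveat.* Tiling four spatially separate plots into one
torus is a modelling device — translations that wrap across plot seams mix
plots. The layout is configurable (`2x2`, `1x4`, …), recorded in every
output, and treated as part of the analysis configuration rather than a
hidden constant.

*Multiplicity.* OTU × habitat tests are reported marginally at P ≤ 0.05,
matching standard practice for this analysis; a Benjamini–Hochberg layer
can be applied downstream but is not the default.

## Bipartite network and modularity

Edges connect each stage to the OTUs occurring in it; the default weight is
the OTU's summed per-sample relative abundance within the stage (raw-count
and presence weights available). Q is Newman's weighted modularity computed
on the bipartite graph's weighted adjacency; `detect_communities` uses
seeded Louvain (networkx) and reports the resolution-1 Q of the partition
it finds, so Q values are comparable across runs whatever resolution
steered the search. Determinism: a fixed seed fully determines the
partition. Barber-style bipartite modularity was considered; standard
Newman–Louvain is the default because it is what the common
network-visualisation toolchain computes, and the quantity of interest is
the bacteria-vs-fungi *contrast*, which both formulations preserve.

## Ordination

Hellinger transform: entry (i, j) = √(count_ij / depth_i); rows have unit
squared sum, making Euclidean ordination appropriate for closed count data.
RDA regresses the column-centred transformed matrix on column-standardised
predictors and takes the SVD of the fitted values; constrained R² =
tr(Ŷ'Ŷ)/tr(Y'Y), adjusted by Ezekiel's 1 − (1 − R²)(n − 1)/(n − p − 1).
Both raw and adjusted values are always reported. Aspect (circular) is
treated as a single linear predictor by default, mirroring how such tables
are usually reported; a sin/cos decomposition is a documented alternative
the caller can apply before fitting.

Permutation test: unrestricted row permutation of Y, p = (1 + #{perm R² ≥
observed})/(n_perm + 1), 999 permutations by default; per-predictor
p-values from marginal single-predictor RDAs under the same scheme. Exact
validity holds under exchangeable rows.

Hierarchical partitioning: R² (adjusted by default, matching common
practice for this decomposition) is evaluated on all 2^p subsets via the
precomputed Gram matrix (p ≤ 15 enforced; 11 predictors → 2,048 subsets),
then each predictor receives the Chevan–Sutherland level-averaged increment
— the Shapley value of the set function — so contributions sum to the
full-model value to machine precision (asserted at 1e-10 in tests).

## Community summaries

- Rare filter: OTU kept iff total reads / grand total ≥ threshold (default
  1e-4, i.e. 0.01%); the boundary is inclusive because the removal rule is
  "< 0.01%". The filter is idempotent: removing rare OTUs only raises the
  relative abundance of the remainder.
- Core = top 10%, dominant = top 0.5% of OTUs ranked by total reads
  (⌈fraction·|OTUs|⌉, ties broken by OTU id so selection is reproducible).
  Ranking by abundance follows the usage this convention comes from; a
  reads-mass interpretation ("OTUs jointly holding 10% of reads") is
  rejected.
- Kruskal–Wallis uses the tie-corrected H with χ²_{g−1} reference; the
  post-hoc procedure (the pairwise significance bars of richness figures)
  is Dunn's z-test with Holm adjustment — chosen as the standard rank-based
  follow-up, switchable.
- Venn membership is defined on summed counts per stage (> 0), not
  per-quadrat prevalence.
- Accumulation curves are sample-based (random permutations, with an exact
  hypergeometric-expectation mode); a read-based rarefaction expectation is
  also provided since richness-vs-sequences axes are common.

## Synthetic generator

Per-cell intensity of OTU *i*:
base_i · λ^{1[habitat = preferred_i]} · exp(Σ_k β_k u_ik z_k(cell)) ·
exp(σ G_i(cell)), with counts drawn multinomially per quadrat at a
lognormal depth (median 10,000 reads, σ_log = 0.3). Choices and rationale:

- **Multinomial at fixed depth** (not independent negative binomials) makes
  depth normalisation in the torus statistic exactly the right correction;
  over-dispersion can be layered on for robustness studies.
- **Gaussian field on the torus** is synthesised spectrally from the
  circulant covariance with Gaussian kernel in toroidal distance
  (correlation length default 2 cells, σ = 0.5). Exact toroidal
  stationarity means the neutral community's law is invariant under the
  translation group — the calibration test then checks an exact null, and
  any miss is a bug rather than an approximation artifact.
- **Domains**: bacteria-like 1,000 OTUs (specialist fraction 0.50, λ = 4),
  fungi-like 400 OTUs (0.55, λ = 8) — roughly 10× fewer OTUs than a real
  survey of this kind so the full pipeline runs in seconds, with the
  fungal domain generated more specialised to mirror the surveyed
  contrast. λ = 8 at the default depth is comfortably detectable on the
  10×10 grid, λ = 1 is exactly null; the defaults sit either side.
- **Covariates** follow stage-linked means with spatial and i.i.d. noise in
  field-plausible units (pH 5.2–6.4, SOM 42–80 g/kg, elevation
  1450–1550 m, …). The two default drivers (pH, mean elevation) carry
  substantial *within-plot* variation (pH sd 0.25; elevation sd 20 m —
  realistic on 20° mountain slopes). This matters statistically: if every
  covariate varied only between stages, all stage-linked predictors would
  be exactly collinear and no method could attribute the community signal
  to the true drivers; the within-plot component is what makes pH and
  elevation identifiable as the top-ranked predictors.
- **Env responses** use per-OTU standard-normal loadings scaled by a
  per-covariate coefficient (default 0.8 on pH and elevation). Larger
  coefficients are counterproductive: they concentrate composition onto a
  few extreme-responding OTUs and degrade predictor recovery.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: taxonomic structure, the very long rare tail of
real OTU tables (at the default depth nearly every synthetic OTU occurs in
every stage, so Venn regions concentrate in the all-stages cell, unlike
field data with thousands of stage-unique OTUs), OTU–OTU interactions,
over-dispersion beyond multinomial sampling, and any spatial structure
*between* plots (plots are exchangeable by construction).

## Problem sizes and determinism

Default analyses (1,400 OTUs, 100 samples) run in seconds: the torus test
is a single (1,600 × 100)·(100 × n_OTUs) matrix product; hierarchical
partitioning over 2,048 subsets uses Gram-matrix solves. Statistical
checks in the test suite use scaled replicate counts (e.g. 50 directional
replicates, 500 permutation-calibration replicates) chosen so the whole
suite completes in well under a minute while keeping binomial noise bands
tight enough to be meaningful. Every stochastic component takes an explicit
seed (numpy `SeedSequence` spawning), and identical configuration + seed
reproduces outputs byte-for-byte.

## Known limitations

- The composite-torus null treats the tiled layout as the spatial truth;
  associations should be read as robust to within-plot autocorrelation,
  not to unmodelled between-plot gradients.
- Per-predictor permutation p-values are marginal (single-predictor), so
  strongly correlated covariates can all appear significant; hierarchical
  partitioning is the intended tool for apportioning importance.
- Louvain is greedy: on adversarial graphs the reported Q can sit below
  the global optimum (tests bound the gap on small graphs).
- The Kruskal–Wallis χ² reference assumes group sizes large enough for the
  rank statistic's asymptotics; with 25 quadrats per stage this is
  unproblematic, but tiny designs should use exact enumeration.
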