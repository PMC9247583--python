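# soilsucc

Statistical analytics for a recurring design in soil-microbiome field
ecology: amplicon OTU tables sampled on a quadrat grid spanning several
forest-succession stages (e.g. plantation, twice-cut, once-cut and
old-growth stands, each a 100 m × 100 m plot split into twenty-five
20 m × 20 m quadrats). The package answers the question *do bacterial and
fungal taxa distribute randomly across succession stages, or do they show
habitat preferences?* — at the OTU level, at the community level, and in
relation to measured environmental covariates.

It is organised as an analysis project: the library under `src/soilsucc/`
holds every computation, the numbered scripts under `analysis/` run the
study end to end on synthetic data with known ground truth, and the
`soilsucc` command line exposes each stage for use on real tables.

## Methods

**Torus-translation habitat association (OTU level).** For OTU *i* and
habitat *h*, the observed statistic is the mean per-quadrat relative
abundance, T*ᵢₕ* = mean over cells of *h* of (count / sample depth). The
null distribution translates the *habitat map* around the toroidally
wrapped composite lattice (default: four 5×5 plots tiled 2×2 into 10×10),
combined with the map's 180° rotation, mirror image and mirrored rotation —
4·W·H − 1 = 399 transformed maps with the identity excluded. Because whole
rows and columns move together, spatial autocorrelation in both the habitat
mosaic and the community is preserved, unlike a naive shuffle of quadrat
labels (which the test suite shows inflates false positives on
autocorrelated data). A verdict is *positive*/*negative* when the observed
statistic falls above the 1 − α/2 / below the α/2 empirical quantile of
the null (two-tailed, α = 0.05, mid-rank ties).

**Bipartite network modularity (community level).** Stages and OTUs are
nodes; an edge carries OTU *o*'s summed per-sample relative abundance in
stage *h*. Newman's weighted modularity
Q = Σ_c [L_c/m − (D_c/2m)²] of the Louvain partition measures how strongly
OTUs compartmentalise among stages; a fungal Q exceeding the bacterial Q
indicates stronger fungal habitat specificity.

**Constrained ordination and predictor importance.** Counts are
Hellinger-transformed (√ of relative abundance), regressed on 11
standardised covariates (pH, SWC, P, SOM, N, aspect, slope, mean elevation,
convexity, woody-plant abundance WA and richness WR); the constrained
variance fraction R² = tr(Ŷ'Ŷ)/tr(Y'Y) is tested by Monte Carlo
permutation (999 row permutations of Y, global and per-predictor), and each
predictor's independent contribution comes from Chevan–Sutherland
hierarchical partitioning over all 2¹¹ predictor subsets (a Shapley
decomposition, so contributions sum exactly to the full-model R²).

**Community summaries.** Rare-OTU filter (overall relative abundance
< 0.01% removed), core (top 10% of OTUs by total reads) and dominant (top
0.5%) subsets, per-quadrat richness compared across stages by tie-corrected
Kruskal–Wallis with Dunn/Holm post hoc, Venn partitioning of OTUs among
stages, and sample-based species-accumulation curves (random or exact
hypergeometric).

**Synthetic generator.** `soilsucc.synth` draws multinomial counts at
lognormal quadrat depths from per-cell intensities combining lognormal OTU
abundances, a preference multiplier λ for specialist OTUs, environmental
responses, and a Gaussian random field synthesised spectrally on the torus
— so a neutral community's law is exactly invariant under the translation
group, making the torus test's null calibration verifiable to its nominal
level.

## Worked example

```sh
python analysis/01_simulate.py            # 4 plots x 25 quadrats, 2 domains
python analysis/03_torus_associations.py  # OTU-level habitat preference
python analysis/04_network_modularity.py  # community-level modularity
```

prints, for the default scenario (seed 1; fungi-like OTUs generated with a
higher specialist fraction and preference multiplier than bacteria-like):

```
bacteria: 256/385 tested specialists recovered with their true habitat (66.5%)
fungi: 166/203 tested specialists recovered with their true habitat (81.8%)
bacteria: 636/721 OTUs associated with >=1 stage (88.21%)
fungi: 310/333 OTUs associated with >=1 stage (93.09%)
...
fungi Q (0.470) > bacteria Q (0.355) — fungi-like OTUs compartmentalise more strongly
```

The association percentages count OTUs with at least one non-null torus
verdict: with environmentally driven composition plus specialists, most
OTUs show some preference, and the generated fungal domain shows more of it
than the bacterial one — by both the OTU-level percentage and the network
modularity, the same qualitative contrast the method is designed to
surface. `analysis/05_rda_hierarchical_partitioning.py` then reports the
constrained variance (~80% here, permutation p = 0.001) and ranks pH and
mean elevation — the generator's true drivers — top in independent
contribution.

The same stages run on real tables via the CLI, e.g.

```sh
soilsucc validate --counts counts.tsv --meta meta.tsv --env env.tsv
soilsucc torus --counts counts.tsv --meta meta.tsv --layout 2x2 --out assoc.tsv
soilsucc run --config run.yaml        # whole pipeline, provenance-stamped
```

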