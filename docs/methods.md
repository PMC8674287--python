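# Methods

This note documents the statistical procedures, default parameters and
numerical conventions of `florahom`, and what the synthetic-world tests do
and do not demonstrate about real checklist data.

## Data model and cleaning

The unit of analysis is the (region, species, status) checklist record with
status `native` or `naturalized`. Cleaning applies, in order:

1. **Name canonicalization** — whitespace collapse, genus capitalized,
   epithets lower-cased. No synonym resolution is attempted; names are
   assumed pre-resolved against a taxonomic backbone.
2. **Hybrid removal** — names containing the multiplication sign, an infix
   " x " token, or the word "hybrid" are excluded. This is a pragmatic
   lexical proxy; it cannot catch hybrids written as plain binomials.
3. **Infraspecific collapse** — records are reduced to the binomial
   (subspecies and varieties inherit the species' status).
4. **Status-conflict resolution** — a species recorded as both native and
   naturalized *in the same region* has both records dropped and reported.
   By default the exclusion is per (species, region); a stricter global
   switch (`CleaningRules.global_conflict_exclusion`) removes the species
   everywhere. The per-region default is the least destructive reading of a
   conflicting-source situation and keeps unambiguous records elsewhere.

Cleaning is idempotent, and every exclusion is returned in a report rather
than silently applied. The presence structure requires each region to keep
at least one native species, and a cell can never be native and naturalized
at once.

## Similarity and the homogenization index

Taxonomic similarity is the Simpson index `1 − min(b,c)/(a+min(b,c))`,
chosen because it is insensitive to richness differences and nestedness;
the Sørensen index `2a/(2a+b+c)` is exposed as an alternative sensitivity
setting everywhere an index choice appears (including the offset-stabilized
H below, which uses the same 0.001 offset for either index). Phylogenetic
versions substitute summed branch lengths of the spanned rooted subtrees
(`A` shared, `B`/`C` unique). Branch classification convention: a branch is
spanned by a flora when at least one flora member descends from it; if the
Newick assigns the root edge a length, that edge is spanned by every
nonempty flora. The same convention (root-inclusive) applies to Faith PD,
so PD of a single tip is its root-to-tip path length.

The homogenization index is `H = ln((Sim_comb + ε)/(Sim_nat + ε))` with
ε = 0.001 (configurable). The offset only matters for near-zero
similarities, where it shrinks otherwise unbounded log-ratios.

Pairs whose similarity is undefined (an empty effective flora, possible
under scenario filters) are flagged and excluded from downstream fits with
counts logged, never fatal.

**Scenario filters** restrict the naturalized species considered for a pair:
`native_to_one` keeps only species native to the other member of the pair
(such additions can only raise similarity — the property tests assert
H ≥ 0 pairwise), and `non_native_to_both` keeps only species native to
neither member (these raise similarity when they arrive in both regions and
lower it when they arrive in one).

**Widely-naturalized sensitivity** — `remove_widely_naturalized` ranks
species by the number of regions where they are naturalized and removes the
top (or bottom) ⌈decile·S⌉ from the naturalized matrix only. Ties are broken
lexicographically by species name, a documented arbitrary choice.

## Distances

Geographic distance is the haversine great-circle distance between region
centroids on a sphere of radius 6371.0088 km. Centroid-to-centroid distance
stands in for border-to-border distance throughout (the two are nearly
perfectly collinear at continental scales).

Climatic distance: the 19 bioclimatic variables are Yeo-Johnson transformed
per column (chosen over Box-Cox because several derived variables can be
zero or negative), z-scaled, and decomposed by PCA. Each loading vector is
oriented so its largest-magnitude coefficient is positive, removing the
run-to-run sign ambiguity of eigenvectors. Region centroids in the space of
the first three components give the climatic distance (Euclidean over the
three axes); PC1-only and PC2-only distances are also produced because in
data of this kind the first axis is dominated by temperature and the second
by precipitation. Climate tables may carry one row per region or repeated
cell-level rows; cells are averaged after projection.

## Distance decay and halving distances

Similarity is regressed on distance with a log-link binomial-family GLM,
`E[Sim] = exp(α + βd)`. Because similarities are continuous proportions
rather than binomial counts, the family is used in a quasi-likelihood
sense; a weighted log-linear least-squares fit (weights = similarity, which
mirrors the IRLS weighting at small means) serves as starting values and as
a fallback, and agrees with the GLM exactly on noiseless exponential data.
For the geographic predictor the intercept is fixed at α = 0 — complete
similarity at zero distance — by dropping the constant term; for climatic
predictors the intercept is free. Zero similarities are retained: the log
link constrains the mean, not the data. The halving distance is
`ln 2 / (−β)`, defined only for negative slopes; nonnegative slopes yield a
no-halving error (reported as NaN in batch tables).

## Matrix regression (MRM)

Response and predictor matrices are vectorized over the strict lower
triangle and fitted by OLS. Because pairs sharing a region are not
independent, significance comes from simultaneously permuting rows and
columns of the response matrix, refitting, and comparing coefficient
magnitudes: `p = (1 + #{|β*| ≥ |β|}) / (n_perm + 1)`, two-sided with the
small-sample +1 correction. Defaults: 999 permutations and a mandatory
explicit seed. Continuous predictors are centered before interaction
products are formed to tame collinearity; binary dummies enter raw.
Administrative relations enter as two mutually exclusive dummy matrices
(same country; dependency/colonial link) with "no relation" as the omitted
baseline. The pipeline's response is the H matrix; similarity-level
responses can be passed directly to `mrm_fit`.

Decay-slope contrasts across administrative categories fit
`H ~ distance × category` on the vectorized pairs; the contrast is the
difference of per-category slopes, with significance from the same response
permutation scheme (a parametric t-test on the slope difference is
available via `method="parametric"`).

Calibration: under an exchangeable response independent of the predictors
the permutation test is exact, and the suite verifies a 5% type-I error
within binomial tolerance over 500 simulations.

## Region-level analysis

Per region: mean pairwise H (taxonomic and phylogenetic, flagged pairs
excluded), native/naturalized richness and Faith PD, the endemic proportion
(natives occurring natively nowhere else *in the dataset* — endemism is
dataset-internal, no external flags), the donor score (mean number of other
regions where the region's natives are naturalized), area and insularity.
Hotspots are reported as a ranked table of mean H; no interpolation or
mapping is performed.

The region regression models mean H on these covariates with richness/PD,
donor score and area natural-log transformed (no offset — the quantities
must be strictly positive, and the fit refuses zeros rather than fudging
them) and all predictors z-scaled for comparability. Spatial
autocorrelation is absorbed by an optional autocovariate: the
inverse-distance-weighted mean of the response over neighbours within a
radius, defaulting to the smallest radius at which no region is isolated.
The residual diagnostic is Moran's I with inverse-distance weights; the
suite verifies that adding the autocovariate reduces it on spatially
autocorrelated synthetic responses. Neighborhood radius and weighting are
exposed because no single convention is canonical.

## Synthetic world

The generator produces a scaled-down analogue of a global checklist
compilation, with every stochastic step driven by one seed (bit-for-bit
reproducible). Defaults: 200 regions in 20 countries grouped into 5
empires, 3000 species, native-similarity halving scale 1800 km, marginal
occupancy 0.02, climate-match weight 1.0, administrative boost 5,
introduction rate 0.01.

**Regions and countries.** Centroids are drawn area-uniformly on the sphere
within ±66° latitude. Countries are spatially coherent k-means clusters of
the centroids, except that a fraction of regions (default 0.4) are
*exclaves* assigned to a random country — emulating overseas territories
and settler-state holdings, which in real administrative checklists place
many same-country region pairs at intercontinental distances. Region areas
are log-normal around a 15,000 km² median and about a quarter of regions
are islands, matching the scale of real region registries. Countries are
partitioned into empires; colonial ties connect countries within an empire,
plus a few extra dependency pairs.

**Climate.** Two latent gradients — thermal (declining with absolute
latitude) and moisture (an independent smooth field) — are mapped to the 19
pseudo-bioclimatic variables: a mutually correlated temperature block
(seasonality variables loading negatively) and a skewed, strictly positive
precipitation block. This reproduces the property that PCA axis 1 is
temperature-dominated and axis 2 precipitation-dominated, without any
raster data.

**Native floras.** For each species a latent Gaussian vector over regions
is thresholded at the occupancy quantile. The inter-region correlation of
the latent field is chosen by numerically inverting the bivariate-normal
conditional exceedance probability so that the expected shared fraction of
two floras at distance d equals `exp(−d ln2 / L)` with L the declared decay
scale. Since Simpson similarity of comparably rich floras approximates the
shared fraction, L is by construction the native halving distance; the
recovery test confirms the fitted value stays within 25% at 200 regions.
(At distances beyond where the target drops below the marginal occupancy
the field correlation floors at zero, so very distant pairs plateau at
chance-level similarity — a mild flattening that the low-mean weighting of
the binomial fit largely ignores.) An infinite decay scale is interpreted
as "no spatial structure" (independent occupancy). Species niches are
Gaussian in the two latent climate gradients (default SD 2.0 latent units,
deliberately wide) centered on the species' highest-suitability region, and
trim occupancy at the climatic range edge via a locally raised threshold.

**Naturalizations.** A species can be introduced into any region where it
is not native. The donor is the nearest same-country native region if one
exists, else the nearest administratively linked native region, else the
nearest native region — reflecting the dominance of within-country and
within-empire trade. The introduction probability is
`introduction_rate × exp(−climate_match_weight × climatic distance to
donor)`, multiplied by `admin_boost` when donor and recipient are
administratively linked, clipped to [0, 1]. With the defaults the
naturalized records come to roughly a fifth of the native records. Ground
truth (per-species core region and every introduction with its donor) is
returned alongside.

**What the synthetic tests show and what they do not.** Passing recovery
tests demonstrates that the estimators detect the effects they target at
realistic sample sizes and that the pipeline is internally consistent. The
generator omits taxonomic error, uneven sampling effort, abundance
structure, regional extinctions, phylogenetic niche conservatism and
temporal invasion dynamics, so the tests say nothing about robustness to
those features of real data.

## Problem sizes and numerical choices

The default reference world (200 regions, 3000 species) was chosen so a
complete pipeline run — 19,900 pairs with phylogenetic similarities and a
999-permutation MRM — completes in well under a minute on one CPU; the
recovery suites use 50 replicate worlds of 100 regions with 199
permutations, a standard size for permutation-test power checks. Pair-level
vectorization works on the strict lower triangle in row-major order;
permutations index into the original matrix rather than copying it. The
PSD repair of the latent correlation matrix clips eigenvalues at 1e-10 and
rescales the diagonal. Reported percentage changes in similarity
back-transform the log-ratio per pair, `100·(exp(H) − 1)`, before taking
medians — the natural inverse of H as a log-response ratio.

## Known limitations

- The hybrid detector is lexical and conservative.
- "Log-binomial GLM" on continuous proportions has no unique definition;
  the quasi-likelihood choice here is standard but not the only one, and
  slope standard errors should be treated as descriptive.
- The MRM assumes linear effects; curvature in H versus distance can leak
  into correlated dummy predictors (visible in compact-country synthetic
  worlds without exclaves).
- Climatic distances depend on the transform family; per-variable manual
  transforms are not reproduced.
- The CLI's stage subcommands rerun upstream stages in memory when invoked
  standalone (except `decay`, which consumes written artifacts); `all` is
  the intended entry point.
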