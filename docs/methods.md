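# Methods

This note documents the modelling assumptions, the synthetic-data generator,
the numerical choices, and the known limitations of `naturadist`.

## The analysis model

The unit of analysis is a (species, candidate-recipient-region) pair; the
candidate set for a species is every region outside its native range, and the
binary outcome records whether the species is naturalized there. The fixed
part of the model contains, for each of the six donor–recipient distances, a
linear and a quadratic term; species identity and recipient-region identity
enter as crossed random intercepts to absorb the non-independence of the many
rows each contributes.

The link is the complementary log-log, `cloglog(p) = log(−log(1−p))`,
appropriate for data where failures vastly outnumber successes: unlike the
logit it is asymmetric, approaching 0 more slowly than 1. An intercept-only
cloglog model has the closed form α = log(−log(1−q)) at outcome prevalence
q, which the test suite uses as an exact anchor.

**Standardization.** Each distance is divided by its sample SD (n−1
denominator) but *not* centred. The quadratic column is the square of the
scaled linear column, not separately scaled. Two properties follow: a zero
ecological distance remains exactly zero after scaling (so "peak at zero"
is a statement about the data's natural origin), and the fitted quadratic
peaks at x* = −β1/(2β2) in standardized units, with the raw-unit peak equal
to x* times the scaling factor.

**Bidirectional vs unidirectional distances.** PC_Temp, PC_Prec, HMI and
flora-diversity distances are signed (recipient minus area-weighted donor
mean; the sign encodes direction). Phylogenetic dissimilarity and centroid
distance are non-negative area-weighted means over donors. Donor weighting
uses region area in both cases. The flora-diversity distance is a single
subtraction of area-corrected residuals — recipient minus the *donor-range
union* (the pooled flora and summed area of all native regions) — rather
than a per-donor weighted mean; the per-donor variant is available through
`flora_distance_mode="per_donor"`.

## Distance ingredients

**Climate axes.** The 19 per-cell bioclimatic variables are first passed
through a monotone normalizing transform chosen per variable to minimize
|sample skewness| among identity, shifted log, shifted square root, and
Box-Cox (a more complex transform must beat the simpler one by more than
√(6/n), roughly the sampling SD of skewness, so near-ties keep the simplest
choice). Transformed variables are scaled to mean 0 / SD 1 and a PCA is
fitted *on cells*; region climate is the unweighted mean of its cells'
scores on the first two axes (each overlapping cell counts once in full —
no sub-cell area weighting). Axis signs are fixed so the first axis
correlates positively with annual mean temperature and the second with
annual precipitation; higher scores therefore mean warmer/less-seasonal and
wetter/less-seasonal conditions.

**Diversity.** Taxonomic diversity is native species richness; phylogenetic
diversity is Faith's PD, the total branch length of the minimal subtree
connecting the community *and the root*. Including the root path makes
single-species PD equal the species' root distance, avoiding zero-PD
degeneracies. Species absent from the tree are grafted as new tips at the
root of their genus (the MRCA of congeners; for a monotypic genus, the
congener's parent node), with pendant length equal to that node's depth so
the tree stays ultrametric — zero-length pendants would contribute nothing
to PD. A family-root fallback covers species with no congener; species
resolvable to neither raise an error listing them.

**Area correction.** Because diversity scales with area, log(PD) and
log(richness) are regressed on log(area) by OLS and the residuals serve as
area-corrected diversity. The regression pools region records and species
donor-union records by default (`scope="pooled"`), since both kinds of unit
feed the same downstream comparison; separate-scope fits are exposed as a
switch. Units with zero richness are excluded from the fit with a warning
and get NaN residuals, never silent imputation.

**Dissimilarity.** Simpson (turnover-only) dissimilarity
min(b,c)/(a+min(b,c)), with species counts (taxonomic) or shared/unique
branch lengths of the two communities' root-spanning subtrees
(phylogenetic). A community nested in another has dissimilarity 0 — users
expecting nested floras to differ should note this is the defining property
of the Simpson family. The root edge, if present, is shared by all
non-empty communities. Pairwise region values are cached per unordered pair
(the cache is semantically invisible).

**Geography.** Haversine great-circle distance on a sphere of radius
6371 km between region centroids; no ellipsoid correction (the error is far
below the resolution of the analysis).

## Fitting

The GLM path is iteratively reweighted least squares, converged when the
maximum absolute score falls below 1e−8 or the relative log-likelihood
change below 1e−10 (followed by two polishing steps so the estimate is
pinned to the optimum rather than the plateau). Rank-deficient designs
raise an error naming the collinear columns; complete separation (vanishing
deviance with diverging coefficients, or |β| > 1000 mid-iteration) raises a
convergence error rather than returning meaningless estimates. η is clipped
to [−30, 3.5] and fitted probabilities to (1e−10, 1−1e−10) for numerical
stability.

The GLMM path is penalized quasi-likelihood: each outer step solves the
working linear mixed model through Henderson's mixed-model equations and
updates the two variance components by an effective-degrees-of-freedom REML
step. Because every row belongs to exactly one species and one region, the
equations have arrow structure — the block for the largest grouping factor
is diagonal — and are solved by Schur elimination of that block, making the
per-iteration cost linear in the number of levels of the large factor. The
variance fixed point converges geometrically, so the iteration applies
guarded Aitken extrapolation (only for contracting sequences, multiplier
capped at 9×, step clamped to [0.2, 5]× the current value); components
collapsing below 1e−4 for several consecutive steps are pinned to the zero
boundary with a warning. Convergence requires |Δβ| < 1e−5 and a relative
variance change < 1e−3. By default a Laplace refinement then re-optimizes
the variance components against the Laplace-approximate marginal likelihood
(Nelder-Mead on the log-variances, with the fixed effects and random-effect
modes profiled by inner penalized IRLS); large simulation loops may disable
it, as the PQL solution is adequate there. On simulated data the refined
estimates agree closely with R's `glmmTMB` (cross-checked in the test
suite). Fixed-effect covariance comes from the fixed-effect block of the
inverse mixed-model equations, the usual PQL approximation. With both
variance components constrained to zero the fit reduces to the GLM.

Wald z-tests are two-sided with normal CIs (multiplier 1.959964); no
multiplicity adjustment is applied. Partial-effect curves hold every other
predictor at the mean of its scaled linear column (the quadratic
contribution uses that mean squared) and set random effects to zero.

## Importance partitioning

The marginal (fixed-effect) R² is σ²_f / (σ²_f + σ²_species + σ²_region +
σ²_d), where σ²_f is the variance of the fixed linear predictor over the
data and σ²_d the link-specific distribution variance. For the cloglog link
the theoretical σ²_d is π²/6 — the variance of the standard Gumbel latent
variable, by analogy with π²/3 for the logit; the delta flavour instead
averages the observation-level delta-method variance μ(1−μ)/(dμ/dη)².

Each distance forms a group of two terms (linear + quadratic). All 2⁶
subset models are fitted and each group's independent contribution is the
level-weighted average of its R² gain over subsets not containing it — the
classic hierarchical-partitioning weights, equal to the Shapley value of
R². Shares are reported as percent of the full model's fixed-effect R² and
sum to 100% per replicate by construction. Negative contributions (possible
under suppression) are reported as-is, not truncated. Subset models are
fitted without random effects by default: the partition compares
fixed-effect structures within a replicate, and at the bootstrap replicate
size (5000 rows) variance components are weakly identified anyway; a GLMM
path is available. Bootstrap replicates draw rows uniformly *without*
replacement, independently across replicates, all seeded.

## Shape scenarios

The signs and significance of (β1, β2) map each distance to a qualitative
shape: for bidirectional distances, directional preference (a/e), an
off-center optimum (b/d), or a similarity optimum at zero (c); for
unidirectional distances, monotone dissimilarity preference (f/j), an
intermediate-distance optimum (g/i), or similarity preference (h). "β = 0"
is operationalized as "not significant at α" (default 0.05, two-sided
Wald), since fitted coefficients are never exactly zero. A significant
*positive* quadratic (U-shape) falls outside the framework and is labelled
`monotone-unclassified` rather than forced into a class. For unidirectional
distances a significant negative quadratic with a non-positive (or
non-significant) linear term puts the peak at or below zero distance and
collapses to similarity-favored (h). Scenarios with an interior optimum
(b, d, g/i) are exactly those for which the peak x* = −β1/(2β2) is valid.

## The synthetic world

The generator emulates the statistical structure of a global
naturalization dataset, not any real geography:

- **Regions** have log-normal areas (default log-mean 10, log-SD 1.2,
  i.e. a median around 2×10⁴ km² with heavy tails), centroids clustered
  around a few continental centers on the sphere, and a Bernoulli island
  flag.
- **Climate cells** derive from latent regional temperature / precipitation
  / seasonality fields tied to latitude; the 19 bioclim-style variables are
  noisy linear mixtures of these latents, with the precipitation-family
  variables exponentiated so several variables are strongly right-skewed
  (|skew| > 1), as in real bioclimatic layers. HMI is a logistic transform
  of a latent development field, supported on (0, 1).
- **The phylogeny** is an ultrametric binary tree built from Yule
  (pure-birth) waiting times. A pure-birth prior spreads branch length
  evenly across epochs, as in large angiosperm radiations; a Kingman
  coalescent prior was rejected because its deep-epoch-dominated trees
  decouple PD from richness, which real floras do not show. Genus and
  family labels are assigned by cutting the tree at 25% and 60% of its
  depth, so congeners are clades and grafting has a ground truth.
- **Native floras** follow a climatic-niche model: each species' 2-d niche
  optimum evolves by Brownian motion along the tree (so related species
  have similar niches, and the distance metrics are realistically
  correlated); occupancy probability increases with log area and decays
  with squared climate mismatch in units of `niche_breadth` regional SDs.
  Every species keeps at least its best-matching region, and realized
  richness follows a species–area power law.
- **Outcomes** are drawn from the same cloglog model the analysis fits,
  with known coefficients and crossed random intercepts
  (σ_species = σ_region = 0.3 by default). The default coefficient set
  mirrors the qualitative pattern the framework is designed to detect — a
  dominant negative quadratic on PC_Temp (−1.32), a strong negative linear
  effect of the flora-diversity distance (−1.82), a positive-then-saturating
  HMI effect (0.39/−0.09), moderate wet-side optimum for PC_Prec
  (0.53/−0.20), similarity-favored dissimilarity (−0.45/−0.07) and an
  intermediate geographic optimum (0.95/−0.12). Two values are package
  choices for desk-scale identifiability: the flora-PD quadratic is −0.10
  (a negligible-but-negative curvature) and the PC_Temp linear term +0.15;
  both were fixed at design time. The default intercept (−4.5) was
  calibrated once so the default world's outcome prevalence is ≈0.04,
  preserving the strong class imbalance that motivates the cloglog link.
- **Random-number streams** are split per table (tree, regions, floras,
  outcomes) from one seed, so regenerating one table never perturbs the
  others, and identical config+seed reproduces every table bit for bit.

**What passing tests do and do not show.** The generator reproduces the
*statistical shape* of the real problem (correlated skewed climate,
species–area structure, phylogenetic niche signal, rare outcomes with
crossed heterogeneity). It does not reproduce real geographic shapes,
actual floras, introduction history, or spatial autocorrelation beyond the
continent clustering; parameter-recovery results therefore validate the
estimation machinery, not any empirical claim about real naturalization
data.

## Problem sizes

The default demo world uses 60 regions × 300 species (≈1.6×10⁴ rows); the
package's full synthetic study, used by the acceptance checks, uses 100
regions × 1100 species (≈10⁵ rows), with coefficient-recovery replicates of
2×10⁴ rows and importance bootstraps of 99 replicates × 5000 rows. These
sizes keep a complete run on one CPU in the minutes range while leaving all
effects comfortably identified.

## Known limitations

- PQL is approximate for binary data: variance components of factors with
  very few events per level (here, species at low prevalence) are
  noticeably attenuated even though fixed effects and their CIs remain
  well calibrated; the Laplace refinement reduces but does not remove this.
- The area-correction regression scope (pooled vs separate) and the
  donor-union reading of the flora-diversity distance are documented
  choices with switches, not settled facts of the method.
- Nearest-boundary geographic distance (an alternative to centroid
  distance) requires polygon geometry and is out of scope; centroid
  distance is the only geographic metric.
- Real-data ingestion expects pre-exported CSV/Newick tables in the
  documented layout; the package contains no database clients, name
  harmonization, or raster processing.
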