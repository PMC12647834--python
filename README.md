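# naturadist

**Donor–recipient ecological distances and the probability of alien-plant
naturalization.**

Why do alien plant species naturalize in some regions but not others? One
family of hypotheses says pre-adaptation matters: species establish where the
climate, the biota and the human footprint resemble their native (donor)
regions. Another family says *difference* matters: enemy release, the
evolutionary imbalance between high- and low-diversity floras, or simply more
human disturbance in the new range. `naturadist` implements a unified
quantitative framework for asking which of these holds, dimension by
dimension, for macroecological flora data.

## The model

For every species *s* and every candidate recipient region *r* outside its
native range, six donor–recipient distances are computed:

| distance | type | definition |
|---|---|---|
| PC_Temp | bidirectional | recipient minus area-weighted donor mean of the first climate PC (temperature & its seasonality) |
| PC_Prec | bidirectional | same for the second climate PC (precipitation & its seasonality) |
| HMI | bidirectional | difference in mean human-modification index |
| flora PD | bidirectional | difference in area-corrected Faith's phylogenetic diversity of the native floras (recipient minus donor-range union) |
| phylo dissimilarity | unidirectional | area-weighted mean pairwise Simpson phylogenetic dissimilarity β_sim = min(B,C)/(A+min(B,C)) on shared/unique branch lengths |
| geographic | unidirectional | area-weighted mean great-circle distance between region centroids |

The binary outcome y<sub>sr</sub> (naturalized or not) is modelled with a
binomial GLMM using the complementary log-log link (suited to the strong
excess of failures):

```
cloglog P(y=1) = α + Σ_k [ β1_k x_k + β2_k x_k² ] + u_species + u_region
```

with each distance x_k scaled by its sample SD *without centring*, so a zero
distance stays zero and a fitted quadratic peaks at x* = −β1/(2β2). The signs
and significance of (β1, β2) classify each dimension into qualitative shape
scenarios — similarity-favored (peak at zero), directional dissimilarity
(monotone), or an intermediate optimum. Each distance's relative importance
is the combined linear+quadratic share of the marginal (fixed-effect)
R², obtained by hierarchical partitioning over all 2⁶ predictor-group
subsets, bootstrapped over subsamples of the data.

Everything runs end-to-end on a fully synthetic world (regions, climate
grids, phylogeny, floras, outcomes from known coefficients), so the whole
pipeline is testable without any external download; real data can be
ingested from CSV/Newick tables in the same layout.

## Worked example

```bash
naturadist run-all --out runs/demo --seed 1
naturadist report runs/demo
```

or in Python:

```python
from naturadist import PipelineConfig, run_pipeline, report
run = run_pipeline(PipelineConfig(seed=1), "runs/demo")
print(report(run).read_text())
```

On the default synthetic world (60 regions, 300 species, 15,565
species×region rows, outcome prevalence 0.010) the fitted standardized
coefficients recover the generative ones; an excerpt of the demo run's
report:

```
                  term  estimate    se
     pc_temp_quadratic    -1.405 0.213      # generator: -1.32
       flora_pd_linear    -1.918 0.263      # generator: -1.82
            hmi_linear     0.426 0.155      # generator:  0.39
         geo_quadratic    -0.104 0.072      # generator: -0.12
```

Temperature similarity is classified as scenario "c" (optimum at zero
distance) and the flora-diversity and PC_Temp groups carry the largest
median importance shares (34.9% and 28.0% of the fixed-effect R² across
bootstrap replicates at this demo scale — with ~160 naturalization events
the strong linear flora-diversity effect edges out the quadratic
temperature effect; at the full study scale used by the acceptance script,
~10⁵ rows, PC_Temp dominates as the generator encodes).

## Package layout

- `synthetic_world` — regions/climate/HMI grids, Yule phylogeny, niche-driven
  floras, cloglog outcome generator
- `climate_pca` — normality transforms, 19-variable PCA, oriented PC_Temp/PC_Prec
- `flora_diversity` — Faith's PD, tree grafting, donor-union records, area correction
- `beta_diversity` — Simpson taxonomic/phylogenetic dissimilarity
- `distance_engine` — the species × recipient modelling table
- `model` (+ `_glm`, `_glmm`) — design, cloglog GLM/GLMM, Wald tests, partial
  effects, peaks, sensitivity subsets
- `importance` — marginal R², hierarchical partitioning, bootstrap
- `scenarios` — shape-scenario classifier
- `pipeline` / `cli` — orchestration, products, manifest, report

See `docs/methods.md` for the modelling assumptions and numerical choices.
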