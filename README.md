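# climspace

Species diversity analysed **in climate space** rather than geographic
space.  For macroecologists asking why warm, humid regions hold more
species: is it the climate itself, or the fact that those climates cover
more land and are scattered into more, and more isolated, fragments?

## What it does

Given a gridded equal-area world (each cell carrying a suite of climate
variables) and gridded species presence–absence data, the package:

1. **Builds a 2-D climate space** — PCA on the correlation matrix of the
   climate variables; the plane spanned by PC1 and PC2 is gridded into
   equal intervals (20–60 per axis).  Every geographic cell falls in
   exactly one *climate cell*, and each climate cell maps back to many
   geographic cells (Hutchinson's duality).
2. **Measures the geography of each climate** — climate *area* (summed
   land area of member cells, km²), climate *fragments* (connected
   components of member cells under queen/rook adjacency with
   antimeridian wrap), and climate *isolation* (mean great-circle
   distance among fragment centroids; all-pairs and fragment-count
   variants included).
3. **Measures diversity per climate cell** — species richness (union
   over member cells) and the multi-site β-diversity decomposition into
   turnover (Simpson, β<sub>SIM</sub>) and nestedness
   (β<sub>SNE</sub> = β<sub>SOR</sub> − β<sub>SIM</sub>).
4. **Models richness** with a Poisson generalized additive model
   (log link), smooths of log area, isolation, PC1 and PC2 —
   penalized cubic regression splines with basis dimension *k* = 4,
   smoothing parameters chosen by GCV — and **partitions the explained
   deviance** into unique and joint shares of the *geography of climate*
   (area, isolation) versus *climate itself* (PC1, PC2), refitting
   reduced models with frozen smoothing parameters.
5. **Diagnoses and projects** — Moran's I correlograms of residuals in
   climate space, Moran-eigenvector (PCNM) spatial filtering, variance
   inflation factors, the quantile-regression (τ = 0.05/0.95) envelope
   of isolation against |latitude|, and back-projection of model
   residuals from climate to geographic space.

A synthetic-world generator (equal-area grid, spatially autocorrelated
correlated climate fields, niche-based spreading-dye species ranges, and
a direct-Poisson benchmark with known coefficients) provides fully
reproducible inputs at desk scale.

## The model

For climate cell *i* with richness *S<sub>i</sub>* ≥ 1,

```
S_i ~ Poisson(μ_i)
log μ_i = β0 + f_A(log A_i) + f_I(I_i) + f_1(PC1_i) + f_2(PC2_i)
```

where *A* is climate area, *I* isolation, and each *f* a penalized cubic
regression spline (k = 4, second-derivative penalty, per-term λ by GCV:
`n·D/(n − edf)²`).  Fit quality is the proportion of null deviance,
`1 − D/D₀`.  With `D(S)` the proportion of null deviance for predictor
subset `S` (λ frozen from the full fit), the partition is

```
unique(x)       = D(all) − D(all \ {x})
joint_geography = [D(all) − D(all \ {A, I})] − unique(A) − unique(I)
joint_climate   = [D(all) − D(all \ {PC1, PC2})] − unique(PC1) − unique(PC2)
joint_between   = D(all) − Σ unique − joint_geography − joint_climate
```

so the seven components sum to `D(all)` exactly.

## Worked example

```python
import climspace as cs
from climspace.pipeline import assemble_cell_table

world = cs.generate_world(cs.WorldParams(seed=7))          # 24x48 equal-area grid
pca   = cs.fit_pca(world.climate_table())                  # 2 PCs ~ 99.8% variance
space = cs.build_climate_grid(pca.scores, n_intervals=20)
pam, _ = cs.generate_species_ranges(world, space, cs.NicheParams(n_species=150, seed=11))

frags = cs.find_fragments(space, world)
geo   = cs.compute_cell_geography(space, world, frags)
rich  = cs.richness_per_climate_cell(pam, space)
beta  = cs.beta_per_climate_cell(pam, space)
table = assemble_cell_table(space, geo, rich, beta)

res = cs.PoissonGAM.from_cell_table(table).fit()
print(res.summary())
print(res.partition().to_series().round(3))
```

prints

```
Poisson GAM (log link, penalized cubic regression splines)
  n obs: 243    basis dim k: 4
  deviance: 208.3622   null deviance: 782.6843
  proportion of null deviance: 0.7338
  adjusted R2: 0.7179   predicted R2: 0.7289   McFadden R2: 0.3326
  total edf: 10.486   GCV: 0.93654
  term        lambda        edf
  area       100          1.838
  isolation  0.3162       1.997
  pc1        3.162        2.860
  pc2        5.623        2.790

unique_area               0.067
unique_isolation          0.077
unique_pc1                0.046
unique_pc2                0.064
joint_within_geography    0.221
joint_within_climate     -0.005
joint_between_groups      0.263
explained                 0.734
unexplained               0.266
```

Reading: the model explains 73% of the null deviance of richness across
the 243 occupied climate cells; the geography of climate (area +
isolation, unique + joint within the group ≈ 0.37) outweighs climate
itself (≈ 0.11), with a large share (0.26) jointly attributable to both —
the synthetic worlds are built so that richness tracks how common each
climate is, and the partition recovers exactly that.

## Command line

```
climspace all -s seed=3 -s 'resolutions=[20,30]' -s output_dir=out
```

Subcommands `simulate`, `build-space`, `geography`, `diversity`, `fit`,
`partition`, `diagnose`, `project`, `all` run the (deterministic)
pipeline up to the named stage; options come from a YAML config
(`-c config.yaml`) with `-s key=value` overrides.  Every run writes the
resolved config and a checksum manifest beside its CSV/JSON artifacts.

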