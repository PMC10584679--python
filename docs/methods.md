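# Methods

This note records the model, the concrete numerical choices, what the
synthetic data does and does not emulate, and the places where the
design was genuinely open.

## Climate space

The climate space is the plane of the first two principal components of
the per-cell climate variables.  The PCA is computed on the
**correlation matrix** (variables standardized to zero mean, unit sd;
optional log transform for skewed, strictly positive variables), so
variables on different scales contribute equally.  Components are
ordered by variance fraction, and each loading vector's sign is fixed so
its largest-magnitude entry is positive — scores are reproducible to the
bit across runs.

Each axis is split into *n* equal intervals (default 20; 20–60
supported — below ~20 there are too few climate cells to fit nonlinear
models, above ~60 new cells stop appearing).  Axis bounds are the
observed min/max of the scores; bins are half-open with the last bin
closed on the right, so the geographic→climate map is total.  Because
bounds are shared across resolutions, binning at 2*n* intervals nests
exactly inside binning at *n* (tested).  Per-climate-cell PC means are
unweighted arithmetic means over member cells — on an equal-area grid
the area-weighted version coincides.

A raw-variable space (e.g. mean temperature × annual precipitation,
bypassing the PCA) is available through the same gridding code path.

## Geography of climate

*Fragments* are connected components of a climate cell's member
geographic cells.  Adjacency defaults to **queen** (8-neighbour) with
antimeridian wrap and no polar wrap; rook is a config option, and the
choice is exposed because fragment counts depend on it.  Fragment
centroids are area-weighted means of member positions computed via 3-D
unit vectors (no antimeridian or longitude-averaging artifacts).

*Isolation* is the mean great-circle distance over unordered
fragment-centroid pairs; alternatives (mean all-pairs member-cell
distance, fragment count) are computed alongside.  Distances use the
spherical haversine formula with R = 6371.0088 km; the < 0.6% error
versus an ellipsoid is immaterial at climate-cell scale.  Single-fragment
cells take isolation 0 rather than missing so they remain usable as
model predictors; analyses can exclude them (the per-taxon cell counts
reported by such analyses then differ, as expected).  Climate area is
the sum of member-cell land areas and conserves total land area exactly.

## Diversity

Richness of a climate cell is the size of the union of species sets over
its member geographic cells.  Multi-site β-diversity among the member
cells uses the Baselga decomposition: with `b_ij = |i\j|`,
`M = Σ min(b_ij, b_ji)`, `X = Σ max(b_ij, b_ji)` over unordered pairs,
and `K = Σ S_i − S_T`,

    β_SIM = M/(K+M),   β_SOR = (M+X)/(2K+M+X),   β_SNE = β_SOR − β_SIM.

Member cells with zero species are excluded from the site list (they
carry no compositional information and make Sorensen undefined); cells
with fewer than two non-empty sites get missing values.  Because the
multi-site measures depend on the number of sites, an optional seeded
resampling mode (fixed site count, mean over repeated subsamples) is
provided for cross-cell comparability; the default is the direct
computation.

## Richness model

Poisson GAM, log link.  Each predictor (log area by default — the
species–area relationship is conventionally log-linear and the raw-area
alternative is a config flag; isolation untransformed; PC1; PC2) is
standardized internally and enters as a **cubic regression spline** with
k = 4 basis functions in the cardinal (function-values-at-knots)
parameterization, knots at evenly spaced quantiles, natural boundary
conditions (linear extrapolation), and the exact integrated squared
second-derivative penalty `S = D'B⁻¹D`.  A sum-to-zero constraint is
absorbed by a QR null-space reparameterization, so each smooth
contributes k − 1 coefficients and its effective degrees of freedom
cannot exceed k − 1 (= 3).

Estimation is penalized IRLS with step halving; convergence is a
relative deviance change below 1e−9 (hard failure, not silence, on
non-convergence).  Per-term smoothing parameters minimize the GCV score
`n·D(λ)/(n − edf(λ))²` by coordinate descent over a 13-point log-spaced
grid (10⁻⁴…10⁸), up to three sweeps, followed by a ±1-decade local
refinement — deterministic by construction, and within a factor of 10 of
an exhaustive fine-grid search (tested).  The penalty null space of each
centered smooth is the linear function, so as λ → ∞ the model collapses
to the linear Poisson GLM (tested against statsmodels at rel. 1e−3).

Goodness of fit: proportion of null deviance `1 − D/D₀` (headline
metric, appropriate for non-normal errors), adjusted R²
`1 − (n−1)/(n−edf)·(1−R²)` on the response scale, predicted R² (squared
Pearson correlation of fitted vs observed), and McFadden's R²
`1 − ℓ/ℓ₀`.  Cells with zero richness are excluded by default (richness
is modelled as a count ≥ 1), which is why different taxa can be fitted
on different numbers of climate cells.

**Deviance partition.**  Reduced models drop each single predictor and
each predictor group, re-estimating coefficients but *never* smoothing
parameters (λ frozen from the full fit).  The commonality-style algebra
in the README makes the seven components sum to the full model's
proportion of null deviance identically; it is one concrete realization
of "drop each predictor and each pair" and is exposed rather than
hidden because other algebras exist.  Frozen-λ refits can produce small
negative unique components; they are stored as-is and only clamped in
displays.

**Partial residuals** for a term are its centered contribution to the
linear predictor plus the working residuals — "richness not explained by
the other predictors" on the link scale.  Residual maps use deviance
residuals by default (response-scale optional); every geographic cell
inherits the residual of its climate cell through the duality map.

A Poisson GLM with orthogonal polynomial terms (degree 1–3) serves as a
cross-check; on the benchmark its proportion of null deviance agrees
with the GAM within 0.05 (tested).

## Spatial diagnostics

Distances among climate cells are Euclidean in (mean PC1, mean PC2):
the residual autocorrelation of interest is autocorrelation *in climate
space*.  The Moran's I correlogram uses 10 equal-frequency distance
classes with binary weights and two-sided permutation p-values (999
seeded shuffles by default; lower bound 1/(B+1)).

MEM/PCNM axes: distances beyond a truncation threshold (auto = longest
minimum-spanning-tree edge, keeping the neighbour graph connected) are
replaced by 4t; the matrix is Gower double-centered and
eigendecomposed; positive-eigenvalue axes are kept.  On a regular
transect the leading axis is the path-graph half-cosine when the
neighbourhood is wide relative to the spacing; at the minimal (MST)
truncation the 4t plateau mixes in the third harmonic, so exact
sinusoid recovery should not be expected there.  The filtering refit
adds axes greedily (most correlated with current deviance residuals,
as unpenalized linear terms, smooth λs frozen) until the first
correlogram class is non-significant at α = 0.05; headline fit metrics
are always reported from the un-augmented model, since the filters
exist only to check that predictors stay significant without residual
autocorrelation.

VIF is `1/(1 − R²_j)` from OLS of each predictor on the rest (∞, not an
error, under perfect collinearity).  The latitude–isolation envelope is
fitted by linear quantile regression (statsmodels QuantReg pinball-loss
minimization) at τ = 0.05 and 0.95 with an OLS line alongside, at the
finest configured climate-space resolution, where the envelope shape is
best resolved.

## Synthetic worlds

The generator emulates the *structure* of real gridded inputs, not the
Earth.  Latitude bands slice sin(latitude) evenly, so all cells have
equal area and summed climate areas conserve total land area exactly.
Two latent fields — temperature-like (28 − 0.45·|lat| plus a Gaussian
random field) and moisture-like (equatorial bump of scale 25° plus an
independent field) — generate 12 climate variables as fixed linear
blends plus 5% independent noise, so two principal components carry
most of the variance (≈ 99.8% at the defaults; real climate suites are
noisier, the paper-scale figure being ≈ 80%, but downstream code only
needs "two axes dominate").  Random fields are white noise smoothed
with a great-circle Gaussian kernel (length scale 2000 km, sd 3): only
the autocorrelation length matters downstream, so the O(n²) kernel
construction is used for exactness.  Land is the top land-fraction
(default 0.7) of another smooth field, giving contiguous continents.

Species ranges: each species draws a niche optimum uniformly over
*occupied* climate cells (so no climate is structurally empty and GAM
fits stay well-conditioned), marks cells inside a breadth ellipse
(default semi-axes 1.5 PC units) as suitable, and grows a connected
range by spreading dye through suitable neighbours to a lognormal
target size (median ≈ 40 cells).  Species with no suitable cell are
dropped, not retried, to keep seeds reproducible.  Richness per climate
cell then increases with climate commonness by construction — the
dependence the analysis is supposed to recover.  What the generator
does **not** emulate: real coastline geometry, dispersal barriers,
evolutionary history, sampling error in range maps; passing tests show
the *machinery* recovers planted structure, not that the ecological
claims hold for real data.

The direct-Poisson benchmark skips range generation entirely: richness
is drawn from `log μ = β0 + β_A·z(log area) + β_I·z(iso) + β_1·z(PC1)
+ β_2·z(PC2)` on a table of mutually independent predictors
(log-uniform areas 10⁴–10⁷ km², folded-normal isolation of scale
2000 km, standard-normal PCs), with the generating coefficients stored
in a truth record.  Independence matters: with a single active
predictor the partition should attribute the explained share to that
predictor's unique component, which is only an identity when the
predictors share nothing.

## Problem sizes and determinism

Default desk-scale conditions: 24×48 grids (≈ 800 land cells), 150–200
species, 20 climate intervals (≈ 200–250 occupied climate cells), 300
cells and 10–200 replicates for benchmark recovery, 199–999
permutations for Moran tests.  Every stochastic step takes an explicit
seed; identical configs produce byte-identical artifacts (checksummed
manifests, tested).

## Known limitations

- GCV only (no REML); single-λ-per-term grid search can in principle
  miss a narrow GCV minimum between grid refinements.
- No tensor-product smooths or interactions; the predictor set is fixed
  to the four-variable design.
- Fragment isolation is centroid-based; minimum edge-to-edge distance
  between fragments is not implemented.
- GeoTIFF I/O is out of scope; the input contract is the CSV cell
  table / per-variable CSV stack.
- The β-diversity resampling mode reports a mean over subsamples, not a
  full rarefaction curve.
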