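# Methods

This note records the statistical and geometric conventions implemented in
`rangeocc`, and the reasoning behind the less obvious choices. Everything
here is testable against the synthetic generator, whose ground truth uses
exactly these definitions.

## 1. Study standardization

A *study* is one metacommunity: a set of sites surveyed for presence/absence
in several years. Surveys are rarely balanced, so each study is reduced to a
comparable core before any occupancy is computed.

**Site matching.** In the default *grid* mode, sites are binned into a
square grid whose resolution is one fifth of the mean of the study's x- and
y-extents. Cells with fewer sites than half the mean sites-per-cell are
discarded (reading "sparse cells" against the pooled distribution of all
sampled cells). In *exact* mode, sites are matched by coordinates rounded to
9 decimals, so a site that moved is treated as two different sites.

**Reference-year pair.** For every pair of years at least 10 calendar years
apart, co-occurrence is the number of matched sites sampled in both years
(in grid mode, summed per cell as the smaller of the two per-cell site
counts — a matched-pairs count rather than a union). Pairs with
co-occurrence above 90% of the maximum are eligible; the longest-duration
pair wins, with earliest start as the tie-break. Studies with no eligible
pair are dropped.

**Year filtering.** Between the reference years, a year is retained only if
it covers more than 90% of the matched sites; years with fewer sampled
sites than half the mean across retained years are also dropped, unless
removing them would shrink the span below 10 years. Where several sampling
methods coexist, only the modal method is kept; where a year contains
repeated visits, effort is rarefied to one combined sample per site-year.

## 2. Occupancy change

Retained years are split at the temporal midpoint into an early and a late
period; a year falling exactly on the midpoint belongs to neither. Periods
are balanced to the same number of years by trimming towards the extremes
(earliest k early years, latest k late years). Within each rarefaction
iteration, every year is subsampled to the minimum number of sites across
retained years; a warning is raised below 4 sites.

Occupancy is the proportion of site-year samples occupied, so each period
contributes `nsamp = n_sites × n_years_per_period` Bernoulli samples. The
change Δ = p_late − p_early lies in [−1, 1] and is analysed through the odd
transform y = sign(Δ)·√|Δ|, which decompresses the dense region near zero
while preserving sign and the ±1 boundary. Species absent in both periods
are excluded; species are additionally classed as lost, gained, or
persisting (up / down / stable) from the raw occupancies.

Worked units: a species occupying one of 4 samples early and none late has
|Δ| = 0.25; with 100 samples per period, 0.01; complete loss and complete
colonization give Δ = −1 and +1 exactly.

## 3. Range size

Occurrence records are cleaned before any estimate: missing coordinates;
fossil, material-sample and living-collection bases; coordinate uncertainty
above 100 km; any raised gazetteer-style flag; and per-species duplicates
within 0.01-degree cells (first record kept). All geometry is planar and
equal-area — synthetic data uses kilometres; geographic coordinates must be
projected upstream.

- **AOO** is the number of occupied grid cells at 10, 50 and 100 km
  (floor-based binning, so it is exactly reproducible). Coarsening can only
  merge cells: aoo_100 ≤ aoo_50 ≤ aoo_10.
- **EOO** is the area of an alpha hull (Delaunay triangles whose
  circumradius is at most alpha = 6 coordinate units, unioned; disjoint
  polygons allowed) for species with more than three distinct points, and
  the union of 10-km disks around points otherwise. As alpha grows the
  alpha hull converges to the convex hull; the disk union avoids
  double-counting overlaps.

The model covariate is log₁₀ range size centred on the global mean, so the
overall intercept refers to an average-ranged species.

## 4. Protection

Protected areas carry a status, an establishment year and a flag for
biosphere reserves. Admissible areas have status designated, inscribed or
established, are not biosphere reserves, and (in the main analysis) were
established strictly before the first late-period year — protection that
arrived during the late period cannot explain the change leading up to it.
Point records are buffered to disks of their recorded area. Two per-study
metrics are computed: the proportion of matched sites inside admissible
areas (boundary counts as inside), and the proportion of the sites'
convex-hull extent covered. A fallback assigns protection from a verbal
region description when per-site coordinates are unavailable, leaving large
ambiguous regions "unknown" (excluded from protection models).

## 5. The hierarchical model

For species j in study i with transformed change y_ij and centred log₁₀
range size z_j:

    y_ij ~ Normal(μ_ij, σ_i)
    μ_ij = x_ij'β + u0_i + u1_i · z_j
    (u0_i, u1_i) ~ BivariateNormal(0, T(τ0, τ1, ρ))
    log σ_i = η0 + η1 · log nsamp_i

The variance submodel reflects sampling noise: losing a species from one of
nsamp samples moves occupancy by 1/nsamp, so residual scatter shrinks with
effort (η1 ≈ −0.5 under binomial sampling on the transformed scale). The
fixed-effects design x_ij is cell-means coded; variants add per-realm
intercepts and slopes, and protection or six z-scored study covariates
(absolute central latitude, regional richness, extent area, nsamp, duration,
start year) as main effects plus range-size interactions per realm.

**Inference.** β and the (u0_i, u1_i) are jointly Gaussian given the five
hyperparameters, so they are marginalized analytically (per-study 2×2
Woodbury identities; the study covariance enters through its Cholesky
factor, which remains well behaved as τ → 0). An affine-invariant ensemble
sampler (32 walkers) then explores (log τ0, log τ1, atanh ρ, η0, η1)
against the exact marginal likelihood plus weakly informative priors:
Normal(0, 5²) on β and the η's, HalfNormal(1) on the τ's, uniform on ρ.
After burn-in and thinning, β and the study effects are drawn exactly from
their conditional Gaussian posteriors for every retained hyperparameter
draw. Convergence is monitored with rank-normalized R-hat across walkers
(threshold 1.05) and effective sample sizes; non-convergence warns and flags
the fit rather than failing.

A study's range-size slope is the sum of its fixed-effect contrast and its
u1_i draw; a study is called positive/negative-significant when the 95%
credible interval of that sum excludes zero. Refitting across rarefaction
iterations gives the sensitivity of the overall slope to site subsampling.

## 6. Synthetic generator and validation

The generator draws per-study effects and per-species range sizes, forms
target occupancy changes from the model above, and realizes them as
presence/absence surveys by rounding p·nsamp occupied samples per period.
Rounding adds noise of order 1/nsamp on the occupancy scale — the same
order as the generating σ_i — so end-to-end recovery of β1 and η1 is
possible and checked. Per-study site counts are varied over half an order of
magnitude to keep η1 identifiable. Companion generators produce occurrence
point sets with exact AOO targets (with optional labelled contaminants that
the cleaning filters must remove exactly) and protected-area polygons
covering a chosen fraction of sites.

Validation rests on: the worked occupancy-change units above; brute-force
enumeration oracles for reference-pair selection (grid and exact) on 100
random toy studies; a 20-replicate recovery study (95% CI for β1 must cover
the truth in ≥ 90% of replicates; η1 posterior mean within ±0.1 at 100
studies); AOO monotonicity on 1,000 random clouds and the alpha-hull →
convex-hull limit; generator round-trips; and a closed-form
weighted-least-squares comparison in the no-pooling limit τ0 = τ1 = 0.
`scripts/acceptance.py` recomputes all of these from scratch.
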