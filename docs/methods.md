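# Methods

## Scope and data model

The package analyses panels of administrative units (provinces, lattice
cells) observed at a small number of survey waves. The outcome is a
prevalence fraction in [0, 1] — here the comorbidity prevalence: the share
of respondents aged ≥ 45 reporting two or more of 14 chronic conditions —
modelled as a continuous response throughout, which matches how such
provincial prevalences are treated in the spatial-regression literature.
Units carry WGS84 centroids and optional polygons; observations carry a
named covariate vector (an exposure, annual-mean PM2.5 in µg/m³, plus
controls). Individual records, when available, are aggregated unweighted:
y(unit, year) = #{age-eligible and comorbid}/#{age-eligible}; unit-years
with no eligible respondents are dropped with a warning rather than
imputed, because every downstream statistic requires an observed outcome.

## Spatial weights

Contiguity weights are binary and symmetric: queen (any shared boundary
point) or rook (shared segment of positive length), computed exactly from
polygon boundaries. Centroid schemes (k-nearest-neighbour, inverse
distance, fixed band) use haversine great-circle distances with Earth
radius 6371 km — at provincial extents a planar degree approximation would
distort distances by several percent. kNN distance ties are broken by
ascending unit id so construction is deterministic. Row standardization
divides each nonempty row by its sum and is idempotent; islands
(zero-neighbour units) pass through with a warning and are reported NS by
local statistics. The pipeline default is queen contiguity on polygons,
falling back to kNN(4) for point-only inputs, which cannot produce islands.

## Autocorrelation statistics and inference

Moran's I and LISA default to row-standardized weights, General G and Gi\*
to raw binary/distance weights, matching each statistic family's
conventional use; all are overridable. Analytic inference for the global
statistics uses the exact first two moments of the permutation
(randomization) distribution — for Moran's I the kurtosis-dependent
randomization variance, for General G the Getis-Ord moment formula — and
the test suite verifies both against exhaustive enumeration of all n!
relabelings on small fields. A seeded Monte-Carlo permutation path avoids
the normal approximation entirely. All tests are two-tailed at α = 0.05 by
default, with report annotations also at 0.1.

The permutation and analytic p-values agree closely in the significance
range (verified within 0.02 at n = 100 on autocorrelated fields). In the
mid-range (p ≈ 0.5–0.9) they can differ by up to ~0.04 at n = 100 because
the permutation null of Moran's I is right-skewed (skewness ≈ 0.3 on a
10×10 queen lattice) while the analytic path is a normal approximation;
this is a property of the approximation, not an implementation error, and
shrinks as n grows.

Local Moran uses I_i = n(x_i − x̄)Σ_j w_ij(x_j − x̄)/Σ_k(x_k − x̄)², so that
Σ_i I_i = S0·I, with conditional-permutation p-values (the value at i held
fixed) and Anselin quadrant classification of significant units by the
signs of the centered value and its spatial lag. No multiplicity
correction is applied by default — an optional Benjamini-Hochberg flag
exists — since local cluster maps are conventionally reported uncorrected.
Gi\* is the self-inclusive variant (w_ii = 1) with the population standard
deviation in the denominator; it is already a z-score and is binned at
|z| ≥ 1.645/1.96/2.576.

## Local regression family

GWR, TWR and GTWR share one engine differing only in the metric:
Δu² + Δv², Δt², or Δu² + Δv² + τ·Δt². Longitude/latitude are projected to
planar km by an equirectangular projection about the study-area centroid
before any kernel computation — adequate at provincial scale and free of a
projection-library dependency. Kernels are gaussian exp(−d²/b²) (default;
strictly positive weights keep local designs well conditioned) and
bisquare. The adaptive bandwidth at i is the distance to the q-th nearest
observation in the model metric, self included; ties at the q-th distance
share the tied bandwidth, and a zero bandwidth (possible for TWR when q is
below the per-wave count) degenerates to an indicator on coincident
points. Local standard errors use σ̂² = RSS/(n − tr S) with the rows
C_i = (XᵀW_iX)⁻¹XᵀW_i, and pseudo-t values are tested two-tailed with
n − tr S degrees of freedom, uncorrected (a flag controls α). Covariates
are not standardized before fitting (coefficients stay in interpretable
per-unit terms); a standardize flag exists for conditioning.

Bandwidth selection minimises AICc by golden-section search on the integer
neighbour count in [k+3, n] (memoised, with the final bracket swept
exhaustively); the test suite checks the result against exhaustive grid
search. For GTWR, τ is searched on an outer grid of 7 half-decade points,
10²–10⁵ km²/yr². The upper limit is deliberate: beyond 10⁵ one year
outweighs several hundred km, which on a domain a few thousand km across
reduces GTWR to disconnected per-wave fits and lets AICc select
degenerate solutions. R² is defined as 1 − RSS/TSS for all models (for
local models RSS + explained variation need not add to TSS), AdjR² uses
tr S effective parameters, and one AICc definition with tr S = k+1 for OLS
keeps the four-model comparison coherent. An AICc gap above 3 is flagged
as a meaningful fit difference.

## Synthetic reference process

The generator emulates the geometry of a national provincial panel — 30
units at 4 waves (2011/13/15/18) with 7 regressors — as a 10×3 lattice of
300-km cells, an east-west-elongated domain. Defaults, chosen once as
realistic for that setting and then frozen:

- **Exposure**: pm25 = 50 + 20·sin(π·v̄) − 1·(t − t0) + N(0, 18²) µg/m³.
  The smooth component runs north-south (pollution concentrated at one
  latitude band), the drift is a secular decline, and the large
  idiosyncratic term reflects how strongly real provinces deviate from any
  smooth surface (nationally observed annual means span roughly 12–82).
- **Coefficient surface**: β_pm25(ū, t) = 0.01·(0.1 + 0.4·ū + 0.03·(t − t0))
  per µg/m³ — largest at the eastern edge and growing over time, spanning
  about 0.001–0.007. The 0.01 scale keeps the linear predictor, and hence
  prevalence, inside (0, 1); an unscaled surface of order 0.1–0.4 applied
  to a ~50 µg/m³ exposure would clip essentially every observation.
- **Orthogonal gradients, by design**: the exposure's smooth spatial
  pattern (north-south) is deliberately placed orthogonal to the
  coefficient gradient (west-east). If both ran along the same axis, the
  within-window coefficient gradient would be absorbed into the local
  exposure slope — the surface would be unidentifiable to any kernel
  estimator, with local estimates anti-correlated with the truth wherever
  the exposure gradient reverses.
- **Noise**: ε ~ N(0, 0.018²) on the linear predictor, the binomial
  standard error of a prevalence near 0.3 estimated from ~700 respondents
  per province-wave. Outcomes are clipped to [0.01, 0.99]; a clip rate
  above 20% logs a warning that effects are too large.
- **Controls**: six i.i.d. N(0, 1) covariates with constant coefficient
  0.01, isolating the exposure surface as the recovery target.

Individual-record simulation draws condition counts from a zero-inflated
mixture calibrated so P(count ≥ 2) equals the target prevalence exactly,
then assigns that many of the 14 condition flags uniformly; ages are
uniform on [45, 90]. Every generator is a pure function of (spec, seed);
the frozen reference fixture in `tests/fixtures/reference/` is regenerated
bit-identically by `stpanel simulate --seed 20240222`.

What the generator does **not** emulate: survey sampling design and
attrition, spatially correlated controls, binomial (rather than Gaussian)
outcome noise, irregular polygon geometry, missing data. Passing recovery
tests therefore demonstrate correctness of the estimators under the stated
process, not robustness to those real-data features.

## Numerical choices and degenerate inputs

Local systems are solved by explicit inversion of the (k+1)×(k+1) weighted
normal matrix with a condition-number guard (> 10¹² raises a
singular-design error advising a larger bandwidth). AICc is undefined when
n − tr S − 2 ≤ 0 (raised as a domain error; reported as NaN for toy-sized
OLS fits). Zero-RSS fits return AICc = −∞ so perfect fits sort first.
Constant fields raise degenerate-field errors for Moran/LISA/Gi\*; a
constant field's General G equals its expectation with z = 0 by
convention. Exports use shortest-round-trip float formatting and sorted
JSON keys so identical configurations yield byte-identical artifacts.

## Known limitations

- The equirectangular projection degrades near the poles and for
  continental-scale domains spanning many degrees of latitude.
- AICc tends to favour local models liberally at small n; under truly
  constant coefficients the expected behaviour (verified in tests) is only
  that OLS stays within the meaningful margin in a majority of replicates.
- The τ grid is coarse by design; τ is a nuisance scale, not an estimand.
- Local pseudo-t inference ignores the smoothing bias of kernel estimates
  and multiple testing across units.
- No multiscale (per-covariate bandwidth) extension, no spatial
  econometric (lag/error) models, no bootstrap intervals.
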