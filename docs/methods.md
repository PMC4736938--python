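# Methods

This note documents the models, defaults and numerical choices behind
`icesurvey`, and what its synthetic scenario does and does not emulate.

## Study system

The virtual seascape is a 27 x 20 lattice of 25 x 25 km survey units with
a mainland band along the southern edge, an 8-cell cape, a coastal
partial-habitat gradient (R = 0.35 / 0.6 / 0.85 in the first three water
rows) and a handful of island/shoal cells. This yields exactly J = 505
habitat-bearing units with total habitat area Σ a_j ≈ 294 000 km² — the
scale of a large Arctic shelf study area — so the default species totals
(380 000 ringed seals, 19 800 bearded seals, expected 1000 polar bears)
imply overall densities of about 1.29, 0.07 and 0.003 animals km⁻².

Twelve survey strata partition the units: units within 50 km of land form
ten alongshore nearshore strata; the remainder is split into southern and
northern offshore strata. Geographic covariates (distance to land,
northing, easting) are computed from unit centroids; distance to land is
the distance to the nearest fully-land cell (for all-water grids the
convention is distance to the southern lattice edge).

Real coastlines, airports, sea-ice covariates and telemetry-based
resource-selection surfaces are *not* emulated: the scenario reproduces
the statistical structure that drives estimator performance (nearshore/
offshore and alongshore density gradients, spatial autocorrelation,
overdispersion, coverage geometry), not the geography.

## Population generation

Stratum density levels are free parameters; the defaults give ringed seals
a nearshore-high, west-high pattern and bearded seals an offshore-high,
south-high pattern, each rescaled by a single constant so Σ a_j d_j equals
the species total exactly. The polar-bear relative-use surface w_j is an
exponentiated smoothed Gaussian field (Gaussian kernel range 100 km,
log-scale SD 0.75 — enough heterogeneity to be patchy without emptying
half the grid), scaled so Σ c·w_j equals the expected total.

Initial densities are smoothed by the row-stochastic matrix **W**
(diagonal 2, rook neighbours 1, rows standardised); no re-normalisation is
applied after smoothing, so totals can drift by a fraction of a percent at
habitat boundaries. Expected abundance is

    λ_j = a_j · exp(log d*_j + η_j + ε_j)

with ε_j ~ N(0, 0.1) read as *variance* 0.1 (precision 10, matching the
precision-based Gamma prior convention used in estimation; configurable).
η is drawn from a reduced-rank ICAR: Q = degree − adjacency, K holds the
leading m eigenvectors of the Moran operator restricted to the complement
of the intercept, and η = Kα with α ~ N(0, (τ_η K'QK)⁻¹), τ_η = 5.
The generation rank defaults to m = min(50, ceil(0.1 J)) = 50; the rank
controls the spatial scale of patchiness and is not identified by any
stated quantity. Zero smoothed densities on habitat are floored at 1e-12
before the log. A 1e-10 jitter stabilises the Cholesky of K'QK, whose
smallest eigenvalues can be near machine precision on small lattices.

Realized abundance N_j ~ Poisson(λ_j) is drawn once per replicate;
surveys then *thin* this realization (n_j ~ Binomial(N_j, A_j),
C_j ~ Binomial(n_j, p_js)), which is marginally identical to drawing
counts directly as Poisson(A_j p_js λ_j) but keeps the true N available
for scoring.

## Survey designs and effort

Each flight is a ~980 km polyline (7840 km for 8 flights, 11 760 for 12).
Exact track placement is a package convention, since only flight counts,
lengths and the nearshore-effort gradient are identified: long flights are
out-and-back "hairpins" of two north-south legs (perpendicular to the
coast) with the 2·n legs evenly spaced east-west and hairpins alternately
anchored at the coast and the far edge; coastal flights are east-west
hairpins inside the nearshore band, staggered alongshore. Legs are clipped
to the habitat extent, so the 12-flight evenly-spread design flies 978.1 km
per flight (0.2% under nominal); all other designs hit 980 km exactly.
The nine-design catalogue crosses 4/8/12 flights with 0/2/4/6 coastal
flights (A1-A2, B1-B3, C1-C4).

Photographic coverage is exact polygon geometry (no rasterisation): tracks
are buffered at half the photo-swath width (0.470 km x 0.84, flat caps),
unioned — so overlapping swaths count once — and intersected with each
unit. A_j is photographed area divided by *habitat* area a_j (capped at 1),
so that A_j λ_j equals photographed area x density; the alternative
(dividing by raw cell area) would understate coverage in partial-habitat
cells.

The preferential-sampling covariate ("samp.dens") is a Gaussian-product
KDE of sampled area at surveyed-unit centroids, evaluated at all centroids
and divided by its mean. The default bandwidth is the per-axis normal
reference rule (weighted SD x n_eff^(-1/6)); a fixed bandwidth in km can
be supplied. Degenerate spreads fall back to one cell width.

## Detection priors

Data generation uses point detectabilities (availability 0.48 bearded,
0.65 ringed, 1.0 bears; thermal detection 0.94). Estimation instead uses
a Monte-Carlo sample of 1000 draws of p_js = a_js x p_s built from a
Beta(71, 5) prior on p_s (kept as stated even though the underlying 66/70
double-sampling counts would suggest Beta(67, 5)) and a per-species
availability prior. The bearded availability prior is logit-Gaussian with
location solved numerically (Gauss-Hermite, 61 nodes; Brent root find) so
its mean is exactly 0.48; logit-scale SD defaults to 0.3, a stand-in for
an unpublished telemetry posterior. Ringed draws are the bearded draws
rescaled to mean 0.65 (draws pushed above 1 are truncated and counted);
bears are a point mass at 1. This generation/estimation asymmetry is
intentional and is what makes seal credible-interval coverage
conservative (above nominal).

## Estimation model and sampler

Counts follow C_j ~ Poisson(A_j p_js λ_j) with
λ = **R** exp(Xβ + η + ε): the offset uses the habitat *proportion* R_j,
so the intercept carries log(animals per fully-habitat unit). This is the
scale at which the coefficient prior is calibrated — with an
area-in-km² offset the intercept would sit at log-density scale and the
prior would materially distort sparse-data fits.

Fixed-effect sets: "covs" (dist.land, sqrt(dist.land), northing, easting,
easting x northing; continuous columns centred/scaled by grid mean/SD),
"stratum" (11 dummies + intercept), "samp.dens". Priors:
τ_η, τ_ε ~ Gamma(shape 1, rate 0.01); β gets the covariate-adaptive
Gaussian prior with precision 0.01·Xc'Xc (Xc column-centred) plus a
diffuse level component (precision 1e-4). The pure g-prior form
0.01·X'X would also shrink the *level* of the fitted log intensity; at
seal scales (mean log intensity ≈ 6.7) that pressure escapes through the
confounded detection parameter — p_js climbs into its prior's upper tail
and total abundance is biased low by ~25% — so the level is left diffuse
while contrasts keep the intended shrinkage.

One Gibbs sweep updates: (i) the per-unit log intensity on surveyed units
by vectorised random-walk Metropolis (per-unit proposal scales tuned in an
adapt phase toward 30-40% acceptance in batches of 50, multiplicative
updates clipped to e^±0.4, frozen afterwards to preserve detailed
balance); (ii) β from its conjugate Gaussian full conditional;
(ii-b) a joint "translation" Metropolis move per fixed-effect column that
shifts β_k and the surveyed log intensities together — residuals are
unchanged, so the acceptance ratio is the Poisson likelihood times the β
prior ratio. Without this block the centred parametrisation mixes
pathologically when counts are sparse (single-digit polar-bear detections):
each unit's likelihood is too weak to pull the log intensity away from its
conditional prior, and β never feels the data. (iii) the ICAR basis
coefficients (when enabled) from their conjugate Gaussian; (iv)-(v) τ_η
and τ_ε from conjugate Gammas; (vi) p_js by independence Metropolis with
the 1000-draw empirical prior as proposal (ratio = likelihood ratio).
Any proposal implying a Poisson mean above 1e12 is rejected and counted
as a numerical-instability event.

Chain schedules: seals 3000 adapt + 60 000 iterations, 10 000 burn-in,
thin 25; polar bears 3000 + 450 000, 50 000 burn-in, thin 200 — both
retain 2000 draws. Replicate experiments and tests use shortened
schedules ("short": 13 000 iterations with 10 000 post-burn, thin 10;
"short_bear": 23 000 with 20 000 post-burn, thin 20; "test": 5000), which
trade Monte-Carlo error for runtime; with the translation block the
shortened chains are well mixed at these data sizes.

Posterior prediction: per retained draw, surveyed units contribute
C_j + Poisson(λ_j (1 − A_j p_js)) and unsurveyed units Poisson(λ_j) with
ε_j redrawn from N(0, 1/τ_ε) — data never inform unsurveyed iid noise, so
it is integrated by simulation. Exponents are capped at 60 before
exponentiation in prediction.

## Replicate experiments and metrics

`run_experiment` crosses species x designs x models over replicates. Per
replicate: bias (N̂ − N)/N, CV = posterior SD / N̂, squared error, and an
indicator that N lies in [q05, q95]. Summaries use medians for bias and
CV (outliers from sparse-data fits are expected), RMSE over replicates,
and mean coverage; failed fits are excluded from the medians but counted.
A master seed feeds a `SeedSequence`; child 0 seeds scenario-level
randomness (bear use surface, detection priors), children 1..n seed the
replicates, each consuming one generator through a fixed stage order, so
single replicates can be re-run in isolation and whole runs are
bit-reproducible.

## What the synthetic scenario shows — and what it does not

Passing tests demonstrate that the estimator is approximately unbiased
with CVs of the expected order under the *assumed* detection parameters,
smooth density gradients and moderate (τ_η = 5, ε-variance 0.1)
patchiness. They do not validate the availability point values themselves,
zero-inflated or strongly aggregated distributions, sea-ice covariate
effects, species misidentification (not modelled), or deviations of real
flights from planned tracks. The interface is the Python API plus the
example scripts; a command-line wrapper was considered and dropped since
every use runs inside a scripted experiment loop anyway.

## Problem sizes used in checks

The shipped checks run the full 505-unit grid with shortened chains and
10-50 replicates (precision and coverage checks), a 100-unit grid with
100 replicates (coefficient recovery), and a 4-unit toy against a dense
quadrature oracle — sizes chosen so the whole suite completes in a few
minutes while leaving Monte-Carlo error well inside the asserted margins.
The full published-scale experiment (9 designs x up to 9 models x 100
replicates x 3 species, ~17 800 fits) is supported by the same
`run_experiment` API with the full chain schedules.
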