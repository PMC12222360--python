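# Methods

This note documents the models, the synthetic study design, the numerical
choices, and the known limitations of the package.

## Occupancy stage

**Likelihoods.** Three single-season models are implemented for ragged
per-site binary detection histories:

* *Independent detections* (``mackenzie``): site likelihood
  `ψ·Π_j p^{y_j}(1−p)^{1−y_j} + (1−ψ)·1[all y_j = 0]`.
* *Markov dependence* (``markov``): local presence `z_j` along consecutive
  replicates of an occupied site follows a two-state chain with
  colonization θ0, persistence θ1 and free initial probability π0;
  detection is Bernoulli(p·z_j). The forward algorithm marginalizes the
  chain; with θ0 = θ1 = π0 = 1 the model reduces exactly to the independent
  one (verified to machine precision in the tests).
* *Abundance-induced heterogeneity* (``royle_nichols``): latent
  `N_i ~ Poisson(λ_i)`, `log λ_i = a0 + aᵀx_i`, replicate detection
  probability `1 − (1−r)^N`. The site likelihood is a truncated Poisson
  sum; the truncation is the smallest K with tail mass < 1e−8 at the
  largest site λ (floor 50). The adaptive K is capped at 1000: beyond the
  cap (reachable only during optimizer excursions to implausibly large λ)
  the truncated sum undershoots the likelihood, which steers the search
  back without affecting converged fits.

Parameters live on unconstrained link scales (log for λ, logit for
r/p/ψ/θ/π0). Fits use BFGS with at least three jittered starts, covariance
from the inverse numerical Hessian, and the small-sample AICc
`−2ℓ + 2k + 2k(k+1)/(n−k−1)` with n = number of sites. A constant-only
independent-detection fit on single-replicate histories is flagged
non-identifiable (ψ and p enter only through their product).

**Replicate length.** Base 2-km segment histories are OR-merged into
longer replicates (trailing remainders dropped). The chosen length is the
smallest at which the independent model beats the Markov comparator by at
least 2 AICc; if never, the maximum is returned with a warning. In the
calibration simulations, "independent" data are generated with equal
colonization and persistence (iid segment presence): abundance
heterogeneity across sites itself mimics within-site correlation, so a
Royle–Nichols-style generator is *not* an independence scenario for this
comparison.

**Goodness of fit.** Pearson's χ² compares observed and expected
detection-count frequencies within replicate-count cohorts (counts are
sufficient for the exchangeable models; expected frequencies come from the
closed-form truncated sums). Cells are pooled smallest-expected-first
until each pooled cell has expected count ≥ 2. The parametric bootstrap
refits the model to each simulated dataset (warm-started at the original
estimates, adaptive truncation); `ĉ = χ²_obs / mean(χ²_boot)`. ĉ has
substantial per-dataset spread at survey-sized designs (its sampling SD is
of order `sqrt(2/df)` relative to 1), so calibration checks average it
over replicate datasets.

**Model selection.** Univariate fits retain covariates with Wald p < 0.05
on the abundance coefficient; pairs with |Pearson r| > 0.70 drop the
member with the higher univariate AICc (ties drop the lexicographically
later name, for determinism); all subsets of the survivors are ranked by
AICc; conditional averaging over the ΔAICc ≤ 2 set weights each model by
`exp(−Δ/2)` and averages each coefficient over the models containing it.

## Covariates

Distances are Euclidean from cell centers on the projected grid;
polylines (rivers) are discretized to points every 100 m before the
distance transform, bounding the error by 50 m. Density surfaces use the
quartic (biweight) kernel `3/(πh²)·(1−(d/h)²)²` with h = 10 km, normalized
to unit mass per unit-weight point (downstream z-scoring makes any scale
convention irrelevant; unit mass is the testable choice). Settlement
points may be weighted by household counts × mean household size 3.7.
Standardization records per-layer (mean, SD) so fitted coefficients can be
mapped back to raw units; repeated standardization composes the records
and is idempotent on the layers. VIF pruning drops the largest-VIF column
while any VIF ≥ 3.

## Home ranges

Telemetry cleaning proceeds per individual: a greedy forward pass drops
fixes implying step speeds above 10 km/h (configurable); a net-displacement
residency rule flags 14-day windows whose start-to-end displacement
exceeds 3× the median windowed displacement and removes their fixes
(a standard dispersal heuristic — the original field protocol's exact
thresholds are not public, so these are declared defaults, all
configurable); the season is restricted to April–October; one fix per day
is kept (nearest local noon). Demographic class is sex × age group with
subadult ≤ 4.0 years at the season start, boundary inclusive.

Bandwidths are diagonal ("separate bandwidths" per axis): each axis uses
the two-stage univariate direct-plug-in pipeline (normal-scale ψ8, then
kernel estimates of ψ6 and ψ4 with Gaussian derivative kernels, linear
binning onto 401 gridpoints for the double sums), with a normal-reference
fallback `H_ii = σ_i²·n^{−1/3}`. A full (off-diagonal) bivariate plug-in is
deliberately out of scope. The UD is a Gaussian-kernel density evaluated
on the analysis grid and renormalized to unit mass; if more than 1% of the
mass falls outside the grid the function refuses and asks for a larger
extent. The 95% isopleth is the density-ranked cell cut — the minimal
cardinality cell set reaching the level (verified against exhaustive
search on small grids) — polygonized from cell rectangles; disjoint parts
are all retained and counted, since fragmented ranges are possible and the
contiguity decision is left to the caller.

## Resource selection

Available points are sampled uniformly within each range-season's
isopleth polygons (area-weighted across parts) at 1 used : 4 available
*per range-season* (the ratio is stated in aggregate in the field; applying
it per group balances availability within groups). Covariates are
extracted at used and available points from the raw rasters and z-scored
with one shared record across the whole design.

The mixed model is a logistic regression with Gaussian random effects for
one grouping factor — home-range/season within individual. Each range
belongs to exactly one individual, so the grouping is implemented as a
single factor keyed by range id; a separate individual-level intercept is
not fitted by default (with one to a few seasons per individual it is
rarely identifiable apart from the range intercept). The marginal
likelihood uses the Laplace approximation per group around the penalized
conditional mode (damped Newton inner loop, warm-started across outer
iterations); fixed effects and covariance parameters (log-SDs, optionally
Cholesky off-diagonals for correlated effects) are optimized jointly by
L-BFGS-B. Fixed-effect covariance is the inverse numerical Hessian in β at
the estimated covariance parameters (the lme4 convention); with no random
effects the exact information matrix `XᵀWX` is used and the fit coincides
with IRLS logistic regression, which the tests verify against statsmodels
GLM.

Random-structure reduction drops correlations first (kept only if a
likelihood-ratio comparison supports them), then slope terms with variance
below 1e−4 on the standardized scale or whose removal changes the
log-likelihood by less than half the χ²₁ critical value; the random
intercept is the floor. Fixed-term testing deletes each covariate-by-class
interaction from the full model (LRT, df = 3 for four classes), removes
non-significant interactions jointly, then tests main effects (df = 1) of
covariates not involved in retained interactions. Reports give β, SE,
Wald Z, `OR = exp(β)` with `CI = exp(β ± 1.96·SE)` (the CI multiplier is
fixed at 1.96), LRT columns, AIC, and Nakagawa R²
(`R²m = σ²_f/(σ²_f+σ²_r+π²/3)`, conditional adds σ²_r), with σ²_f the
variance of the fixed linear predictor over the design. Per-class maps are
`w(x) = exp(β_mainᵀx + β_class + β_intᵀx)`, optionally min–max rescaled to
[0, 1] for display; both the single final model and a model-averaged
prediction path are exposed, since published practice varies on which is
mapped.

## Synthetic study design

Covariate layers are linear SW→NE trends plus Gaussian-filtered white
noise with a configurable correlation range, rescaled into stated value
ranges (precipitation 400–680 mm across the study gradient; NDVI
0.05–0.8; canopy 0–60%). The survey road network is one straight east-west
transect per 8-km site row, giving every site equal road length — the
statistical structure of the real design without its geometry. Surveys
draw latent site abundance Poisson(λ at the site center) and replicate
detections `1−(1−r)^N`, or a presence chain along segments when Markov
parameters are set. Telemetry is drawn by exact rejection sampling from
`exp(βᵀx(s))·k(s−c)` with an isotropic bivariate-Gaussian kernel k
(proposals from k, acceptance from the selection term capped at its grid
maximum); home-range centers are kept 3.5 kernel SDs inside the extent so
essentially the whole range is on the grid.

**What recovery can and cannot show.** Availability defined from the use
distribution (the 95% UD isopleth) feeds selection back into the
availability sample, and a use-weighted home-range kernel enters the
used/available density ratio as an omitted covariate. Both effects
attenuate selection estimates when covariates vary smoothly at the
home-range scale: in the limit of a locally linear covariate field, the
estimated availability absorbs the entire selection signal. The recovery
experiments therefore use covariate fields whose correlation lengths
(300–500 m) are well below both the home-range scale (kernel SD 4 km) and
the KDE bandwidth — the regime in which the isopleth cannot selectively
exclude avoided micro-patches and the design identifies β. The recovery
trial maps the generator's truth onto the design's standardization scale
through the two (landscape and design) z-score records before comparing.
Passing these tests shows the estimator chain is correct *under its own
design assumptions*; it does not certify selection estimates for
covariates that are near-constant within a home range (e.g., regional
rainfall gradients), where attenuation of within-range contrasts is a
property of the design itself, not of the implementation. Real telemetry
also carries serial autocorrelation, fix loss, and habitat-dependent fix
success, none of which the generator emulates.

**Problem sizes.** Recovery experiments use 200 sites × 10 replicates for
the occupancy recovery; 25 replicate surveys of 60–100 sites for the
replicate-length calibration; 200 sites × 10 replicates × 200 bootstrap
draws × 20 datasets for the goodness-of-fit calibration; and a telemetry
design of 2 lions per class × 80 daily fixes with a 64×64 km landscape for
the end-to-end selection recovery (20 seeds). These sizes were chosen so
each check has adequate power while a full validation run stays
comfortably inside an ordinary workstation session.

## Degenerate inputs and tie-breaks

Zero-variance layers refuse to standardize; empty feature sets and empty
road networks raise; r = 0 with an observed detection yields a guarded
large-but-finite negative log-likelihood; singular VIF fits are treated as
infinite VIF; equal-AICc collinearity ties drop the lexicographically
later column; sites whose road length yields no complete replicate are
dropped from aggregated histories; bootstrap refit failure above 10% of
replicates aborts the goodness-of-fit run.
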