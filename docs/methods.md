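# Methods

This document records the statistical models implemented in `zetascape`,
the assumptions behind them, and the numerical choices made in the code.
Everything stated here is computed by the package; nothing is an external
empirical claim.

## Zeta diversity

For a binary site-by-species incidence matrix with *N* sites, the zeta
diversity of order *i* is the expected number of species shared by *i*
sites drawn uniformly without replacement. Because a species occupying
*o* sites is shared by a random *i*-subset with probability
C(*o*, *i*) / C(*N*, *i*), the exact value is

ζᵢ = Σ_species C(o_s, i) / C(N, i),

computed in `zeta_exact` from species occupancies via log-gamma
(`scipy.special.gammaln`) so that large binomial coefficients never
overflow; terms with *o* < *i* are exactly zero. This closed form is
equivalent to full enumeration of all C(*N*, *i*) subsets and is verified
against a brute-force enumeration oracle in the test suite.

`zeta_montecarlo` instead samples site combinations (without replacement
within a combination, combinations drawn independently) and averages the
shared-species counts; it reports the sample standard deviation and
standard error. Sampling uses `numpy` generator `argpartition` draws so
the cost per sample is O(*N*) regardless of order.

**Why keep both.** Exact zeta values at successive orders are smooth,
strongly correlated functions of the same occupancy vector, so ordinary
least-squares inference on a fitted decline curve (confidence intervals,
p-values) is badly miscalibrated when applied to exact values: the
residuals are not independent noise. Monte Carlo zeta reintroduces
independent sampling error of known magnitude, which restores approximate
OLS calibration. The package therefore uses exact zeta for point
estimates and descriptive curves, and Monte Carlo zeta whenever a fit's
*inferential* output (CI coverage, significance of a coefficient) is the
quantity of interest.

Derived quantities:

- **retention rate** at order *i*: ζᵢ / ζᵢ₋₁, the probability that a
  species shared by *i*−1 sites is also in an *i*-th; undefined (NaN)
  when the denominator is zero;
- **normalizations** per sampled combination: Sørensen (shared count over
  mean richness of the combination) and Simpson (shared count over
  minimum richness); Sørensen ≤ Simpson always;
- **beta summary**: γ (pooled richness), mean α (= ζ₁), Whittaker β =
  γ / ζ₁, and a pluggable effective-community-number `n_star`
  (defaulting to Whittaker β).

## Decline-curve fitting

`fit_decline` fits log ζᵢ over a contiguous order window by OLS under
three forms: **exponential** (regressor *i*), **power law** (regressor
log *i*), and **combined** (both). Orders with ζᵢ = 0 cannot enter a log
fit and bound the usable window. Model choice uses AICc, the
small-sample-corrected AIC:

AICc = AIC + 2k(k+1) / (n − k − 1), with k = number of regression
coefficients + 1 (the error variance counts as a parameter).

The correction matters because decline fits typically use n ≤ 10 orders,
where plain AIC systematically favours the extra parameter of the
combined form. The selected form is interpreted as a process diagnosis:
exponential ⇒ stochastic (placement-equivalent) assembly, power law or
combined ⇒ niche-structured assembly. Under the neutral model in which
every species independently occupies each site with probability *p*,
ζᵢ = S·pⁱ exactly in expectation, so the exponential coefficient has the
closed-form target −slope = −ln p; this limit is exercised in the tests.

`breakpoint` splits the orders into a "rare-species" and a
"widespread-species" regime at the first interior maximum of the
retention-rate sequence (retention typically rises as rare species drop
out, then falls or flattens in the widespread regime). If the sequence
is monotone there is no peak; the midpoint order is returned with a
`no_peak` flag. `fit_piecewise` fits the two segments separately; a
segment with fewer than three usable orders is widened toward the other
side, with a warning, rather than fitted degenerately.

## MS-GDM

Multi-site generalized dissimilarity modelling regresses zeta similarity
(or its complement, multi-site dissimilarity) on monotone transforms of
environmental differences aggregated over each sampled site combination.

**I-spline basis.** Each covariate, rescaled to [0, 1], is expanded in
three order-2 monotone I-splines with a single interior knot at 0.5.
These have closed forms: I₁ = 4x(1−x) for x ≤ ½ then 1; I₂ = 2x² then
1 − 2(1−x)²; I₃ = 0 then (2x−1)². Each basis function is 0 at 0, 1 at 1,
and non-decreasing, so any non-negative linear combination is a monotone
transform — the key substantive assumption of GDM, that increasing
environmental difference can only increase (never decrease) expected
compositional dissimilarity.

**Fit.** Responses are 1 − normalized zeta similarity per combination.
Predictors are per-combination ranges (max − min) of each retained
covariate plus the maximum pairwise geographic distance, each I-spline
expanded. Coefficients are estimated by bounded least squares
(`scipy.optimize.lsq_linear`) with coefficients ≥ 0 and a free
intercept. Predictor **importance** is the sum of its three spline
coefficients (= total rise of its fitted partial curve); **variance
explained** is the squared Pearson correlation between fitted and
observed dissimilarity.

**Biotic variants.** `run_model_suite` fits, besides the abiotic model,
variants that add the observed turnover of *another* species category
over the same site combinations as an extra monotone predictor (e.g.
non-endemic turnover predicting endemic turnover). This asks whether one
assemblage's turnover carries information about another's beyond the
shared environment. Combinations are sampled once per order and shared
across model variants, so variance-explained differences between
variants are not sampling noise. Duplicate-sample and
records-per-coefficient diagnostics warn when the design is too small
for the coefficient count.

## Range statistics and co-occurrence

`range_stats` computes per-species occupancy, occupied-elevation range,
mean elevation and maximum pairwise geographic extent.

`perm_anova` tests a statistic across categories with a classical
one-way F statistic (identical to `scipy.stats.f_oneway`) whose null
distribution is obtained by permuting category labels; the p-value uses
the add-one estimator (b+1)/(m+1), so the smallest attainable p with m
permutations is 1/(m+1). Post-hoc pairwise permutation tests are
Holm-corrected (verified against `statsmodels` `multipletests`). NaN
values are dropped before testing.

`c_score` (mean pairwise checkerboard units, normalized to [0, 1]) and
`nodf` (nestedness by overlap and decreasing fill, in [0, 100]) are
computed vectorized and verified against literal loop-based definitions.
A perfectly triangular matrix has NODF = 100; a checkerboard has
NODF = 0 and C-score = 1.

`vif_screen` drops covariates by variance-inflation factor (default
threshold 10), recomputing VIFs after each drop; exactly collinear
covariates give infinite VIF and are dropped first.

## Spatially corrected richness models

Spatial autocorrelation inflates the apparent significance of
environment–richness relationships. The package controls it with
distance-based Moran's eigenvector maps (dbMEM): the site-distance
matrix is truncated at the minimum-spanning-tree's largest edge (the
smallest threshold keeping all sites connected), larger distances are
replaced by 4× the threshold, the resulting matrix is Gower
double-centred, and the eigenvectors with positive eigenvalues form the
spatial predictors. These are orthogonal, centred, and
translation-invariant, as the tests verify directly.

Richness is modelled as a Poisson GLM (log link) on natural cubic
splines of each retained covariate (3 knots at quantiles, giving 2
columns per covariate — enough for a hump, few enough to resist
overfitting 160 sites) plus the dbMEM eigenvectors. Per-covariate
p-values come from likelihood-ratio chi-square tests against the model
without that covariate's columns. A `linearized_slope` (OLS of the log
fitted values on the raw covariate) summarizes direction and magnitude
on the log scale; under a log-linear truth it recovers the generating
slope, which the tests check. Reported fit quality is deviance explained
(1 − residual/null deviance) and McFadden pseudo-R². If the default
IRLS fit fails on sparse counts with many spatial columns, the fit is
retried with L-BFGS, and the convergence flag is propagated honestly.
A hump/monotone classifier on the fitted richness–elevation curve
summarizes the response shape.

## Synthetic island flora

The generator builds a 16 × 10 grid of 8.25-km cells with three
elevation massifs (peak heights 2452, 2456 and 2148 m) plus smooth
random relief. Covariates (rainfall, temperature, terrain roughness,
calcareous fraction) are deterministic functions of elevation and
position plus noise, producing realistic collinearity (e.g. temperature
strongly anti-correlated with elevation), which is why the analysis side
screens by VIF.

Each species category is assembled as a **mixture of a neutral and a
niche process**. Neutral: every species–site occurrence is an
independent Bernoulli draw with a per-species rate. Niche: each species
has a Gaussian suitability profile on elevation (random optimum,
category-level breadth), and occurrence probability follows suitability.
Per-species occupancy rates are drawn from a category-level distribution
(mean target and spread), so occupancy heterogeneity is endogenous.
Calibration of the niche mode is done once per category on the mean
occupancy (a single scaling factor), not per species, so the niche
signal is not calibrated away. The mixture uses shared uniform draws so
that mixture weight 0 and 1 reproduce the pure modes bit-exactly, and
intermediate weights interpolate the same randomness rather than adding
new noise.

`generate_crete_like` produces 1482 non-endemic, 91 neo-endemic and 74
palaeo-endemic species with decreasing occupancy targets (0.08, 0.06,
0.05) and spreads (0.09, 0.06, 0.05), palaeo-endemics the most
niche-restricted. A `scale` argument shrinks species counts
proportionally for fast tests.

**Realism limits.** The generator is a controlled testbed, not a
reconstruction: occurrences are independent across species given the
environment (no direct competition or facilitation), the niche axis is
elevation only, there is no dispersal limitation beyond what the
environmental field induces, and no observational error. Patterns that
require those mechanisms (e.g. strong segregation beyond environmental
filtering) will not appear in synthetic data.

## Numerical and reproducibility choices

- All binomial-coefficient arithmetic in log space (`gammaln`);
  zeta values below ~1e-300 are exactly representable as 0 and treated
  as such by the fitters.
- All randomness flows from `numpy.random.default_rng` seeded explicitly;
  pipeline stages derive sub-seeds by fixed offsets from the study seed,
  so every artifact is byte-reproducible. The pipeline config hash
  excludes the output directory (an output path is not an analytic
  input).
- OLS fits use `numpy.linalg.lstsq`; bounded monotone fits use
  `scipy.optimize.lsq_linear`; GLMs use `statsmodels`.
- Floating-point comparisons in tests use absolute tolerances at the
  scale of accumulated rounding (1e-9 to 1e-12), not loose thresholds.
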