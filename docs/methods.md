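# Methods

## The question and the estimands

Given a table of leaf N, P and N:P observations (one record = one species at
one site) with environmental covariates, the package quantifies how much of
the trait variation is attributable to (i) which species occur where
(across-species variation, "biogeochemical niche") and (ii) plastic or
locally adapted responses of species to their environment (within-species
variation). The estimands are:

* per-species trait-gradient slopes b_i and their density mode,
* occurrence ranges R_i (1–99% quantile spread of site-mean trait values
  over the sites a species occupies, normalized by the overall 1–99% range),
* R²_across and R²_within from the species variation decomposition,
* mixed-model variance components (marginal R², ICC),
* cross-validated R² of RF and LM models on three data versions, and the
  environment-only contribution of RF models (full minus identity-only),
* the commonality partition of site vs species effects.

## Preprocessing

Records with N:P strictly above 70 g N (g P)⁻¹ are removed (extreme ratios
are almost always unit or measurement errors). For the trait gradient
analysis, only species recorded at ≥ 5 distinct sites and sites hosting ≥ 5
distinct species are kept. Both criteria are evaluated on the unfiltered
input and intersected in a single pass; an iterated fixed-point variant is
available (`iterate=True`) because removing a species can push a site below
threshold. The single pass is the default since the rule is stated as two
conditions, not an iteration. The N:P filter runs before the occurrence
filter; the order is observable (an outlier record can prop up a species'
site count) and is covered by a test.

Community means are computed with one vote per record. Without abundance
data this is the only community-weighted mean the sampling design supports;
a mean-of-species-means variant is available for sensitivity checks.

## Trait gradient analysis

All trait values are natural-log transformed first; slopes are invariant to
the log base and to multiplicative unit changes (tested). Site means x̄_j are
arithmetic means of log values over all records at site j (geometric means
on the original scale), recomputed after the occurrence filter, with the
focal species included. For each species, OLS of x_ij on x̄_j gives the slope
b_i, its standard error and a t-based 95% CI; species whose site means are
constant are skipped. The slope-density mode uses a Gaussian KDE with
Silverman bandwidth on a 512-point grid spanning the data ± one bandwidth; a
degenerate (constant) slope sample returns that value directly.

Occurrence ranges are computed on the original scale (ranges of logs would
compress the upper end), using linear-interpolation quantiles. The default
normalization divides by the overall 1–99% range of all site means; dividing
by the overall mean is available (`norm="mean"`) since both conventions
appear in the literature.

The species variation decomposition compares the observed log values with
two modified series: species means substituted for every record
(across-species variation only) and records recentered so every species mean
equals the grand mean (within-species variation only). The squared Pearson
correlations with the observed series equal the between- and within-species
shares of the total sum of squares, so they sum to one; the test suite
asserts this identity against an explicit one-way-ANOVA oracle. Degenerate
cases (no within- or no across-species variance) are reported as 0 with a
flag; a single-species dataset raises.

## Model comparison

Random forests use the ecology-standard parameterization: `mtry` candidate
predictors per split with `mtry = max(1, ⌊(K−1)/3⌋)` (the paper-style rule
made integral), minimum terminal node size 5, and 500 trees by default
(reduced in desk-scale runs; see "Problem sizes"). Performance is the
cross-validated R², computed per held-out fold as 1 − SSE/SST and averaged
over 5 folds; folds are a uniform random partition with sizes differing by
at most one. A pooled-prediction R² is available as an alternative. A fold
with zero target variance raises rather than returning an undefined score.

Recursive feature elimination starts from all predictors and repeatedly
drops the one whose removal costs the least CV R², recording scores for
every nested set down to a single predictor. The final set is the smallest
whose score is within 1 percentage point of the path maximum (`--rfe-tol`);
the elimination score itself uses the per-fold-averaged R². Hyperparameter
tuning (`tune_rf`) minimizes mean CV RMSE with ties broken toward smaller
`mtry`, then larger node size (the more regularized forest).

The comparison grid fits, per trait: RF to site-aggregated means, to
species-centered (within-only) records and to the full records (with
one-hot species/genus/family identity added); LM to the site and within
versions (species effects are absent there by construction); and the LMM to
the full version. The environment-only contribution is RF(environment +
identity) − RF(identity only). Traits are log-transformed before model
fitting by default: concentrations are lognormal-like and the generative
model is additive on logs. Cells that cannot be fitted (e.g. zero
within-species variance in a pure-niche world) are flagged and skipped, not
fatal.

## Mixed model and decompositions

The LMM is `trait ~ covariates + (1 | species)`, fitted by REML
(statsmodels MixedLM). Covariates are z-scored so coefficients are
comparable "normalized effects"; their t-tests use a residual-df
approximation (df = n − p) and are flagged at the 1% level. The target is
Yeo-Johnson transformed by default (λ by maximum likelihood); `"log"` and
no transform are available, and the recovery tests use the log scale because
the generator is exactly Gaussian there. Variance components give marginal
R² = var_fixed/(var_fixed + var_random + var_resid) and both ICC flavors;
the adjusted flavor var_random/(var_random + var_resid) is the default
report. A random-intercept variance estimated at the boundary (including
non-converged boundary profiles, detected as var_random < 1% of var_resid)
is reported as ICC 0 with a warning.

Sequential (type-I) sums of squares are computed by explicit nested
least-squares model comparison rather than formula-interface ANOVA, because
formula machinery reorders terms and the whole point is the order: species
fitted before vs after the environmental terms attribute the shared variance
differently, while residual and total SS are order-invariant. The
commonality partition for two factors uses three OLS fits:
individual_a = R²(A+B) − R²(B), individual_b = R²(A+B) − R²(A),
shared = R²(A) + R²(B) − R²(A+B), unexplained = 1 − R²(A+B); a negative
shared component (suppression) is flagged, not clipped.

## Synthetic data

The generator draws, on the log scale,

    log x_ij = a_i + β_i · m_j + f(E_j) + ε_ij

with site gradient m_j ~ N(0, σ_m²), species baselines
a_i = μ + c·(niche centre) + N(0, σ_sp²), slopes β_i ~ N(β₀, σ_β²),
covariate effects f that are linear or threshold interactions
(effect · sign(E_a·E_b), which has zero linear projection), and residual
noise ε. Values are exponentiated, so concentrations are positive and the
downstream log transform recovers the linear structure exactly. Species
occupy either contiguous windows of the sorted gradient (environmental
filtering; baselines can be coupled to the window centre) or random site
subsets. The within-species gradient term uses the absolute gradient m_j:
centering it per species' occupied window would make the regressor depend on
the occupancy draw and bias trait-gradient slopes upward by k/(k−1) for
k sites per species — an artifact of conditioning, not a property of the
data-generating world being emulated.

Ground truth records the *realized* slopes and within-species variance
fractions (computed from the sample, not the asymptotic σ's), the
informative covariate set and the gradient. One master seed drives named
per-component streams (gradient, occupancy, baselines, slopes, residuals,
each covariate), so components can be resized or regenerated independently
and equal seeds give byte-identical CSVs.

What the generator does **not** emulate: spatially autocorrelated climate
fields, correlated covariates, phylogenetic structure among species
baselines, abundance variation within sites, and measurement error in the
covariates. Passing recovery tests therefore demonstrate correctness of the
estimators under the stated hierarchical model, not robustness to all
features of field compilations.

## Problem sizes and numerical choices

Recovery analyses run at desk scale, chosen as the smallest sizes at which
the Monte Carlo error of each statistic is well below its assertion
tolerance: trait-gradient recovery at 300 species × 20 sites per species
(slopes β ~ N(1, 0.2), residual sd 10% of the within-species signal sd),
ICC/marginal-R² recovery at 200 species × 10 observations, feature
elimination on 80 site means with 3 informative of 12 covariates over
repeated seeded runs, with 50–150 trees per forest in these loops (forests
of this size already stabilize the CV ranking at these n). Slope-mode and
median recovery aggregate the median over 5 replicate datasets to suppress
the sampling noise of the KDE mode. Quantiles interpolate linearly between
order statistics. Ties in RFE candidate scores resolve to the first-listed
predictor; all fold assignments and forests are seeded, making every path
bit-reproducible.

## Known limitations

* Only species random intercepts are modeled (no nested genus/family or
  random slopes); with strong cross-species structure the ICC absorbs it.
* The commonality partition is descriptive: with observational occupancy the
  shared component cannot be causally attributed to either factor.
* CV R² of the identity-only RF is not a consistent estimator of the ICC,
  though the two are compared side by side in the grid, mirroring common
  practice.
* The occurrence filter's single-pass default can leave species/site counts
  slightly below threshold in the filtered table (the iterated variant
  guarantees the thresholds but removes more data).
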