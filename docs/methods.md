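# Methods

`svdlatent` implements a latent-variable analysis of cerebral small vessel
disease (SVD): MRI markers measured in strategic brain regions are treated
as indicators of an underlying SVD construct, which is extracted by
exploratory factor analysis, scored, related to cognitive performance, and
embedded in a structural equation model as a mediator of age and
cardiovascular-risk effects on cognition.  Because participant-level MRI
cohorts of this kind are access-restricted, the package ships a synthetic
cohort generator that reproduces the statistical structure the analysis
assumes, and every stage is validated against that generator.

## Synthetic cohort

### Measurement layer

Thirteen markers are generated: six regional PVS counts (basal ganglia,
frontoparietal, temporal, insular, thalamus, brainstem), two WMH volumes
(periventricular, subcortical), mean white-matter FA and trace, and three
binary microbleed presence flags (lobar, deep, infratentorial).

Continuous indicators follow an orthogonal two-factor model on the z scale,
`z = Λf + Ψ^{1/2}ε` with unit implied variances.  Factor 1 is the SVD
construct (loads WMH, FA [negatively], TR, basal ganglia and thalamus PVS);
factor 2 is a second, non-pathological PVS dimension (frontoparietal,
temporal, insular).  The default loading matrix is the published two-factor
pattern of the nine retained indicators with two deliberate deviations:

* thalamus PVS loads 0.50 on factor 1 instead of the published 0.42.  At
  0.42 the population communality is 0.202 — exactly on the 0.2 pruning
  threshold — and sampling noise at n = 892 would prune a marker the
  analysis is supposed to retain about half the time.  The default builds
  in a stability margin; the loading-recovery experiments that compare
  against the published pattern use that exact pattern, not the cohort
  default.
* brainstem PVS gets weak loadings (0.26, 0.12; h² ≈ 0.08) so that it is
  pruned, as intended.

Microbleed flags arise by thresholding standard-normal liabilities (with
their own factor loadings) at the quantile matching the configured
prevalence (lobar 24%, deep 14%, infratentorial 8%).  This makes the
population tetrachoric/biserial correlations equal products of loadings, so
the mixed-correlation estimators can be validated against the generator.
Liability loadings (lobar 0.21/0.12, deep 0.38/0.08, infratentorial
0.31/0.10) put the population communalities in the published removal order
(lobar < brainstem PVS < infratentorial < deep, all < 0.2) while keeping
deep MB strong enough that its extension loading onto the SVD factor stays
salient (λ × score validity ≈ 0.35 ≥ 0.32).  These two requirements pull in
opposite directions: deep MB's communality sits near the threshold by
construction (the reference analysis itself measured 0.19), so on roughly
one default cohort in five its estimated h² crosses 0.2 and it survives
pruning.  That stochasticity is a property of the analysis at n = 892, not
an implementation artifact.

Raw scales: PVS counts are `mean + sd·z`, rounded and floored at zero
(for the low-count insular region this truncation inflates the mean by
~5% and slightly attenuates its correlations — visible as a recovered
loading near 0.52 rather than 0.57 at n = 892).  WMH volumes are log-normal
with log-scale parameters matched to the reported medians and IQRs
(periventricular median 2351 mm³, IQR 998–6143; subcortical 251, IQR
43–946), so that the downstream Tukey ladder recovers the latent normal
scale exactly.  FA and TR are normal (0.393 ± 0.025; 0.0025 ± 0.0001).

### Structural layer

Standardized structural variables are generated along the acyclic diagram
`X → SVD → GM → cognition` with direct paths `X → GM`, `X → cognition`.
Only the composite pathway effects are published (X→SVD→Cog = −0.043,
X→SVD→GM→Cog = −0.007, X→GM→Cog = −0.018, direct = −0.003 per SD of age);
the individual path coefficients are derived from those products with the
magnitudes set equal wherever the split is underdetermined (|a| = |b| within
a product), signs chosen so the exposure raises SVD and lowers GM and
cognition.  These splits are a synthetic convention, not estimates.
FRS is generated correlated 0.4 with age (it is partly an age function) and
is not given its own structural coefficients; the FRS mediation model is
exercised on the same cohort.

### Cognition and covariates

Ten test scores load 0.65 on latent cognition with a −0.228 mean shift;
with PC1 weights over ten such tests the global composite lands near the
reported mean −0.72 and SD 2.18.  The "cognitively normal" flag (used only
to select the PCA weighting subsample) marks the top 80% of latent
cognition — a stand-in, since no operational definition is available.
Demographic and vascular covariates (sex, race/ethnicity, education, six
sites, language, SBP, medication flags, WHR by sex, log-normal physical
activity, APOE-ε4) match the reported marginal distributions and are
independent of the latent factors by default: the joint
covariate–marker distribution is not published, so the generator asserts
independence rather than inventing confounding.  An opt-in per-site loading
shift supports invariance power experiments; missingness is off by default
with opt-in MCAR rates.

What the generator does *not* emulate: site/scanner effects (beyond the
opt-in shift), non-normal measurement error, count over-dispersion,
confounded covariates, informative missingness.  Tests passing on this
cohort therefore validate the estimators under the model's own assumptions;
they do not certify behaviour on real MRI data.

## Mixed correlation matrix

Pearson for continuous pairs; tetrachoric for binary pairs (two-step ML:
thresholds at the marginal normal quantiles, then Brent root-finding on the
(1,1) orthant probability, which is monotone in ρ; +0.5 continuity
correction on all four cells when any cell is empty); biserial for mixed
pairs (point-biserial rescaled by √(pq)/φ(τ), clamped to [−1, 1] with a
warning).  Such matrices need not be positive definite; wherever an inverse
is required (KMO, factor scores, extension weights) eigenvalues are clipped
at 1e-6 and the matrix re-normalized to unit diagonal, erroring if any entry
moves by more than 0.05.  Factor extraction itself uses minres precisely so
that no inversion — hence no smoothing — is needed.  KMO of an exactly
diagonal matrix is 0/0 and returns 0 with a "not factorable" warning.

## Factor analysis

Minres minimizes the sum of squared off-diagonal residuals of `R − ΛΛᵀ`
over uniquenesses (L-BFGS-B, bounds [0.001, 1], SMC starting values,
ftol 1e-9); loadings come from the leading eigenpairs of the reduced
matrix.  Factor count: Velicer's MAP (minimum average squared partial
correlation after removing k principal components) and VSS (complexity 1
and 2); when they disagree MAP governs with a warning.  Pruning removes the
lowest-communality indicator (< 0.2) and re-estimates the mixed matrix and
fit from scratch after every removal; ties break lexicographically.
Rotation: oblimin (direct quartimin) first; if all inter-factor
correlations are below 0.32 in magnitude the varimax solution is adopted.
Varimax uses Kaiser row-normalization — without it the rotated solution of
the reference pattern's own implied matrix misses the published loadings by
up to 0.04, with it by < 0.005.  The salience threshold (default 0.32) is
inclusive of the boundary.  Extension analysis is regression-based
(`Λ_ext = R_ev W` with W the retained-variable score coefficients,
normalized to correlations with the estimated scores); factor scores use
the regression method `W = R⁻¹ΛΦ` on the smoothed matrix.  Factors are
ordered by variance explained and oriented so each factor's
largest-magnitude loading is positive (which reproduces the negative FA
loading).

## Association models

Gaussian identity-link GLMs (estimated by least squares, their ML solution)
of each cognitive outcome on each factor score with three nested covariate
sets; categorical covariates are reference-coded.  Profile-likelihood 95%
CIs invert the profiled deviance `n·log(RSS(β)/RSS_min)` at the χ²₁
quantile; for the linear model the profile is exactly quadratic, giving
closed-form endpoints that agree with t intervals to < 1% of an SE at
moderate n.  The supplementary per-marker analyses control FDR at 5% within
each cognitive domain by Benjamini–Hochberg.  The MRI/cognition completion
order enters as a binary indicator.  Missing data are handled by listwise
deletion per model.

## Structural equation models

A compact RAM-parameterized engine: directed paths A, symmetric
(co)variances S, `Σ(θ) = F(I−A)⁻¹S(I−A)⁻ᵀFᵀ`.  Estimation minimizes the
normal-theory ML discrepancy with an analytic gradient (finite-difference
checked in tests); χ² = (n−1)·F at the optimum; CFI/RMSEA against the
independence baseline; SRMR over the standardized residuals including the
diagonal.  Free variances are bounded below at 1e-6 and a solution on the
bound is flagged as a Heywood case.  Loading start values are seeded from
the first principal component of the indicator block — constant positive
starts can trap the optimizer in a local minimum when an indicator (FA)
truly loads negatively.  Up to three jittered restarts on non-convergence.
Mean structure is not modelled (covariance-only fitting); the published
solution is standardized, which the covariance structure determines.

Identification: the exogenous-latent variance is fixed at 1 (all loadings
free); once SVD is endogenous its *residual* variance is fixed at 1, and
the reported solution is completely standardized from the implied
variances.  Covariates enter as exogenous variables with paths to all three
endogenous variables (SVD, GM, cognition) and a saturated covariance block —
the adjustment route is not spelled out in the source analysis, so the most
conservative (all-equations) version is used.

Effect decomposition enumerates every directed path from exposure to
outcome; each pathway effect is the product of its standardized
coefficients, `total = direct + Σ pathways` holds algebraically (1e-12).
Proportion mediated is reported in percent of the total.  Bootstrap CIs are
bias-corrected (not BCa — no acceleration term, matching the stated
procedure): z₀ from the fraction of resamples below the point estimate
(ties counted half), endpoints at the Φ(2z₀ ± z_{α/2}) percentiles.  The
reference replication count is 5000; pipeline default is 500 with the
smaller count chosen to keep desk-scale runs in seconds, and the coverage
experiment in the test suite uses 500 resamples × 200 replicates at
n = 2000.

The single-indicator comparison refits the structural model with each
observed indicator in place of the latent mediator.  Because indicator
measurement error attenuates regression paths, the latent model mediates
more and explains more outcome variance — a property the tests check across
generator seeds.

## Multi-group invariance

Six site groups, single-latent measurement model with the three
same-modality residual covariances.  Conventions (which reproduce the
published model degrees of freedom 36/61/96 exactly):

* configural: everything group-specific, latent variance fixed at 1 in each
  group;
* metric: loadings shared; latent variance stays fixed in the first group
  and is freed in the others;
* equal-reliability level: residual variances also shared and the latent
  variance fixed at 1 in every group; residual covariances remain
  group-specific.  (Intercepts are not modelled, so this is not classical
  scalar invariance.)

Nested levels are compared by likelihood-ratio tests.  The scaled
chi-square difference statistic `(T_r c_r − T_f c_f)/c_d` with
`c_d = (df_r c_r − df_f c_f)/(df_r − df_f)` is implemented and unit-tested
against hand arithmetic so externally supplied robust scaling factors can
be used; the synthetic data are multivariate normal, so the engine itself
runs plain ML (scaling factors 1), where the statistic reduces to the
simple χ² difference.

## Problem sizes

Loading-recovery experiments run at n = 100,000 (MC error of a loading
≈ 0.003); SEM parameter recovery at n = 50,000; factor-count, pruning and
invariance checks at the reference n = 892; bootstrap coverage at n = 2,000
with 500 resamples × 200 replicates; invariance type-I calibration at
6 × 300 × 200 replicates.  These sizes put every Monte-Carlo tolerance well
below the effects being checked while keeping any single experiment under a
few minutes on one core.

## Known limitations

* The generator's covariates are independent of the latent factors, so
  covariate adjustment in the synthetic analyses is exercised but not
  stressed (no confounding to remove).
* The second PVS factor induces small cross-modality residual correlations
  among the SVD indicators that the mediation SEM does not model; at
  n = 892 this misfit is negligible (CFI ≈ 1.0) but it is visible as mild
  lack of fit at very large n.
* Tetrachoric estimation uses the two-step estimator (thresholds fixed at
  marginal quantiles), not full joint ML; the difference is far below the
  sampling noise at the sizes used.
* No robust (sandwich) standard errors; bootstrap CIs are the inferential
  route for effects.
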