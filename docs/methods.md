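# Methods

This note records the models implemented in `treegs`, the defaults of the
synthetic trial generator, the numerical choices inside the estimators, and
what the test suite does and does not establish.

## The synthetic trial

The generator emulates a polycross progeny test: 38 maternal families sired by
a 19-father pollen mix, 8 offspring per family on each of 2 sites (608 trees),
laid out in 4 randomized complete blocks, genotyped at 500 biallelic SNPs
(configurable up to several thousand) and phenotyped for height (cm), DBH
(mm), wood density (kg/m³) and acoustic velocity (km/s).

*Genotypes.* Founder dosages are drawn under Hardy–Weinberg at minor allele
frequencies sampled uniformly from (0.05, 0.5); offspring receive one allele
per parent per locus by fair Mendelian sampling.  There is no linkage or LD —
SNPs are independent, which matches an array of well-spaced gene-derived
markers but not dense re-sequencing.

*Traits.* Per-SNP effect vectors are multivariate normal across traits with a
target genetic correlation matrix; breeding values are the centred dosages
times the effects.  The raw breeding values are re-coloured and re-scaled so
the realized additive variances and correlations equal their targets exactly
(the same linear map is applied to the marker effects, so the identity
`true_bv = Z_c β` is preserved to machine precision).  This removes
finite-marker-panel simulation variance from parameter-recovery experiments:
what remains when an estimator misses the target is estimator error.
Phenotype = trait mean + site offset + block effect (SD 0.2 of the trait SD)
+ breeding value + residual.  Default heritabilities (0.46, 0.45, 0.42, 0.41)
and means/SDs are typical of a 19-year-old white spruce polycross test; the
default genetic correlation matrix carries the classic conifer structure of
strongly correlated growth traits (0.7) adversely correlated with wood
density (−0.3).

*Drought response.* Each tree carries a drought-year growth multiplier — a
heritable trait (default mean 0.94 on site 1 and 0.88 on site 2, i.e. 6% and
12% expected growth loss; SD 0.12; h² 0.25) whose genetic correlations with
the trait panel default to (0.5, 0.45, 0.2, 0.05) for height, DBH, density
and acoustic velocity: genetically vigorous trees resist better.  The
multiplier scales expected BAI in the drought year and, with decaying
exponents (0.4, 0.15, 0), in the following years, so resistance, recovery,
resilience and relative resilience all carry genetic signal downstream.

*Ring series.* Expected BAI follows a logistic juvenile trend (plateau
1500 mm², sized to give a ~140 mm DBH tree at age 19) scaled by a lognormal
per-tree vigour factor (SD 0.3), shared lognormal site-year effects (SD 0.05)
and per-tree-year noise (SD 0.05); the series is inverted exactly to ring
widths from the pith.  The year effect of the drought year itself is fixed at
1 — the multiplier *is* that year's deviation; drawing an additional random
climate deviation for the same year would double-count it.  The year-effect
SD is a compromise: the common signal must be strong enough for the dating
check to latch onto, yet weak enough that the injected drought dip remains
identifiable in the site chronology.  Real chronologies have a stronger
common climate signal that is *correlated with measured weather*; here the
non-drought year effects are independent of the generated climate series, so
climate–growth correlations are near zero except through the drought year.
That is a deliberate simplification: passing tests show the bootstrap
machinery is calibrated, not that the generator reproduces dendroclimatic
coherence.

*Climate.* Daily temperature is sinusoidal (Quebec-like seasonal cycle) with
Gaussian noise; precipitation is Bernoulli–Gamma (wet-day probability 0.45,
mean ~4.8 mm/day).  In drought years July–August precipitation is scaled by
0.45, which reliably produces a positive scaled-DC anomaly in those months.

## Drought Code

The daily DC update follows the standard Van Wagner equations exactly as
coded (potential evapotranspiration with the monthly day-length factor table
and the −2.8 °C temperature floor; rain routine for precipitation above
2.8 mm with effective rain 0.83·P − 1.27 and moisture equivalent
800·exp(−DC/400)).  The fire season defaults to April 1 – October 31 with a
fixed spring start value of 15; the overwintering rule is configurable
because operational systems differ and none is canonical for this use.
Monthly DC is the mean of daily values; anomalies are centred/scaled per
calendar month over a configurable baseline, and a month with zero baseline
variance is an error rather than a silent zero.

## Detrending

"Frequency response f" is interpreted the dendro way: the smoothing spline's
amplitude response equals f at a stated wavelength, defaulting to 0.67× the
series length.  The spline is the discrete natural cubic smoothing spline
(Reinsch banded solve); on unit-spaced data it acts as the filter
1/(1 + λ·12(1−cos θ)²/(2+cos θ)), which is solved for λ at θ = 2π/wavelength.
Constants and straight lines are reproduced exactly (they span the penalty
null space), f = 1 is the interpolation limit, and the implementation is
verified against its own frequency response on long sinusoids.  Ratio
detrending requires a strictly positive fitted curve; a non-positive curve
raises with advice rather than producing negative indices.

A caveat the tests quantify: a multi-year growth depression is partially
absorbed by the fitted curve (about a quarter of it at the default
stiffness), so chronology-level dip estimates are conservative.  The pipeline
therefore measures the site-level growth loss as a resistance-style ratio —
drought-year index over the mean of the two preceding years — whose reference
years sit above the locally depressed curve and offset most of the
absorption.

## REML engine

The univariate animal model is estimated by average-information REML run in
the eigenbasis of ZKZ′: after one symmetric eigendecomposition every
iteration is O(n), which is what makes 100-fold cross-validation and
replicate calibration studies affordable.  Each AI step is safeguarded by a
step-halving line search against the REML log-likelihood (falling back to a
scaled-gradient direction), so the log-likelihood is non-decreasing by
construction; if no uphill step exists down to 2⁻⁴⁰, the current point is a
(possibly boundary) optimum and iteration stops.  Convergence is a relative
log-likelihood change below 1e-7 (cap 200 iterations).  Variance components
are floored at 1e-8 of the phenotypic variance.  Standard errors come from
the inverse AI matrix, h² SEs by the delta method.  The additive variance is
tested against σ²ₐ = 0 with the 50:50 χ²₀:χ²₁ boundary mixture.  Breeding
values and their prediction-error SEs are validated in the tests against the
mixed-model equations and the inverse coefficient matrix directly.

The bivariate model is parameterized as per-trait variances plus additive and
residual correlations, optimized over transformed parameters (log variances,
atanh correlations, capped at |z| = 6) with L-BFGS-B; the likelihood is
evaluated through per-eigenvalue 2×2 blocks.  SEs come from a central-
difference Hessian at the optimum, mapped back through the delta method; the
phenotypic correlation and its SE are derived from the components.
Significance uses likelihood-ratio tests refit with r_a (1 df) or r_a and r_e
(2 df) pinned at zero.  Estimates with |r_a| > 0.99 are flagged as boundary
cases — with ~300 trees per site the additive/residual split of a strong
phenotypic correlation is genuinely weakly identified, and the flag is
information, not failure.

Two readings exist in the field for accuracy-style formulas; this package
uses PACC = PA/√h² (with the GBLUP h² as the reference heritability for both
methods) and r_i = √(1 − SE²ᵢ/((1+Fᵢ)σ²ₐ)), clamped at zero with a log when
the prediction-error variance exceeds the denominator.  Both quantities are
exposed separately so either convention can be recomputed.

## Cross-validation and selection

Folds deal individuals round-robin within each family after a seeded shuffle,
so every fold holds roughly 10% of every family and fold sizes within a
family differ by at most one.  Held-out trees keep their row/column of K and
lose only their phenotypes; variance components are re-estimated per training
fold.  PA is the Pearson correlation between held-out phenotypes and their
predicted breeding values.

Selection indices standardize each trait's EBVs to unit variance before
weighting (raw-scale weighting is available behind a flag but makes weights
unit-dependent); the top ceil(p·n) candidates are taken with a deterministic
tie-break (descending score, then ascending id).  Gains are means of the
selected trees' EBVs as a percentage of the phenotypic mean — which inflates
spectacularly for traits whose mean is near zero (relative resilience); the
zero-mean case raises and suggests absolute gains instead.

## Pipeline

`run-all` chains all stages per site, analyzing sites separately (the two
simulated drought episodes differ in year and severity, so pooling would
conflate them); site 2's post-drought window is marked invalid by default,
mimicking a stand thinning in the drought year, so only resistance is
evaluated there and only scenarios without resilience run.  Every output file
carries a hash of the analysis configuration, and all randomness flows from
one seed, making re-runs byte-identical.  Default problem sizes (608 trees,
500 SNPs, 10×10 CV for two traits and two methods) keep a full run around a
minute; these sizes are the package's default study conditions, and larger
panels are a config change, not a code change.

## Known limitations

- No linkage/LD, no selection or drift across generations, no dominance or
  epistasis, and no G×E beyond site mean shifts — sites share the same
  genetic architecture by design.
- Chronology-level dip estimates are conservative under ratio detrending (see
  above); per-tree resistance ratios do not have this problem.
- The bivariate additive/residual decomposition is weakly identified at
  single-site sample sizes; SEs are honest about this, and simulations show
  ~95% coverage of the true genetic correlation at n ≈ 600.
- The A-inverse is computed by dense Cholesky inversion, appropriate for
  trials of hundreds to a few thousand trees, not national evaluations.
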