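# Methods

## The model

For subject *i* with behavioral t-score *y_i* at age 12, monthly airborne
lead exposures *x_ij* (ng/m³, month of life *j* = 1…144) and covariates
*c_i*, the package fits the Gaussian linear distributed lag model

    y_i = α + Σ_j β_j x_ij + c_iᵀγ + ε_i,    ε_i ~ N(0, σ²).

Unconstrained, the 144 lag coefficients are hopelessly unstable: exposures
at neighbouring months are strongly correlated by construction (all twelve
months of a year share one annual estimate, scaled by monitor-derived
monthly factors). The DLM is therefore constrained so that β_j = f(j) is a
smooth function of the month of life, represented in a spline basis with
coefficient vector θ: β = Bθ with B the 144 × K basis matrix. The fit
minimizes

    ‖y − α − XBθ − Cγ‖² + λ θᵀSθ,

where S is a curvature penalty and λ ≥ 0 the smoothing parameter.

### Basis and penalty

The default basis ("cr", every-lag) is a natural cubic regression spline
parameterized by its values at the knots, with a knot at every lag; the
basis matrix evaluated at the knots is then the identity, and S is the
exact integrated squared second derivative assembled from the
Green–Silverman band matrices (S = DᵀB⁻¹D, rank K − 2, null space = affine
functions of lag). An alternative dialect ("ps") uses cubic B-splines on
uniform unclamped knots with a second-order difference penalty; its null
space is likewise affine. The two dialects agree closely on smooth truths
(asserted in the test suite); the default follows the convention of
curvature-penalized regression splines.

### Smoothing selection, edf, inference

λ is chosen by restricted maximum likelihood (default), minimizing the
profiled criterion

    (n − M_p)·log(RSS + λθ̂ᵀSθ̂) + log|XᵀX + λP| − rank(S)·log λ

over log λ ∈ [log 1e−8, log 1e12] by bounded scalar minimization
(tolerance 1e−6 on log λ), where P embeds S in the full coefficient block
and M_p is the number of unpenalized coefficient directions. GCV is
available as an option. The implementation was cross-checked against an
independent penalized-regression fit of the identical design and penalty
(mgcv's REML with a user-supplied penalty): λ, edf, coefficients and
standard errors agree to ~1e−6 relative; one such comparison is frozen
into the test suite.

Model complexity is reported as the **effective degrees of freedom** of the
spline block, the partial trace of (XᵀX + λP)⁻¹XᵀX over the θ columns. It
equals K at λ = 0 and falls monotonically to 2 (the affine null space) as
λ → ∞. Following the study design this package reproduces, a fit whose
selected edf exceeds 20 is refit with at most 20 equally spaced knots and
flagged.

Coefficient uncertainty uses the Bayesian posterior covariance
V = σ̂²(XᵀX + λP)⁻¹ with σ̂² = RSS/(n − edf_total), the standard choice in
penalized smoothing. Per-lag effects are β̂ = Bθ̂ with pointwise
normal-based intervals from the propagated covariance.

### Sensitive windows

A sensitive window is a maximal run of contiguous months whose pointwise
95% CI lies strictly above zero (harmful) or strictly below it
(protective); an interval touching zero exactly does not exclude it.
Windows of length one are allowed; opposite directions never merge. The
intervals are pointwise, so across 144 months some zero-exclusions are
expected by chance under a null curve; the familywise any-window rate is
reported by the simulation tests but deliberately not controlled — window
detection here is exploratory, and simultaneous bands are a non-goal.

Ages are formatted with month of life *m* spanning ages m−1 to m months:
window bounds print as "start−1" to "end" ("birth to 7 months"), and an
age in completed months prints as years + months ("4 years 4 months" for
52 completed months).

## Exposure construction

Scaling factors are per (year, month) pairs — the ratio of that calendar
month's mean monitor concentration to the mean of all raw observations in
the baseline window (2001–2005 by default; a mean-of-monthly-means
denominator is available as a switch). Calendar months with no observation
are filled by linear interpolation of adjacent monthly means and logged
(strict mode errors instead, naming the month). Factors are invariant to
rescaling the whole monitor series.

The annual estimate for year of life *y* is the day-count-weighted mean of
the annual estimates of all residences overlapping [birth + (y−1) yr,
birth + y yr), using actual calendar days (leap days included). Month of
life *j* is attributed to the calendar month containing
birth + (j−1) months. Missing factors or uncovered years produce explicit
NaN cells, logged with subject and month, never silent zeros; subjects
with missing months are dropped (and ledgered) at fit time.

Two exact identities follow from the construction and are enforced in the
tests: per subject-year, mean(monthly exposures) = annual estimate ×
mean(the twelve applicable factors); and the matrix scales linearly in the
annual estimates while the factors are scale-free.

## The synthetic cohort

The generator emulates the structure of a prospective birth-cohort air-lead
study; every downstream stage consumes its output through the same public
interfaces used for real data, and monthly exposures are built by
`leadlag.exposure`, not by a parallel code path.

* **Monitor series** — observations every 3–6 days (uniform random gaps)
  from 2001 through 2016: a seasonal sinusoid (baseline 1.5 ng/m³,
  amplitude 0.5) times a log-normal calendar-month source effect
  (sd 0.6) times log-normal observation noise (sd 0.5). Airborne lead is
  spiky; month-to-month source variability dominating the smooth seasonal
  cycle is what gives the scaling factors their realistic roughness, and
  the multiplicative form keeps concentrations positive without clipping.
* **Exposures** — births uniform over Oct 2001–Jul 2003; per-subject
  log-normal annual estimates with a subject level (log-sd 0.3, centred so
  the realized subject-level median monthly exposure hits the 0.51 ng/m³
  target after scaling), AR(1) year-to-year deviations (ρ = 0.7, stationary
  sd 0.35) giving the temporal collinearity the penalty exists to handle,
  and 0–2 address moves (probabilities 0.5/0.35/0.15) with a log-sd 0.4
  shift at each move, exercising residence-time weighting. Realized pooled
  monthly exposures have median ≈ 0.51 and IQR ≈ 0.6.
* **Covariates** — a single latent factor ties the subject's exposure level
  to maternal education (ordered-probit, levels 19/29/52%), blood lead
  (log-normal, mean 0.57, sd 0.37 µg/dL), deprivation (0.41 ± 0.15, clipped
  to [0,1]), greenspace NDVI (0.54 ± 0.08) and ECAT (0.37 ± 0.10), with
  per-covariate correlations (default ±0.2–0.3) and outcome coefficients of
  a few t-score points; six visit measurements per time-varying covariate
  add small visit noise. Setting the correlations to zero turns
  confounding off; with them on, the marginal exposure–outcome association
  provably differs from the generating curve (asserted at large n).
* **Outcomes** — generated from the exact DLM equation with residual
  SD 10 (the t-score scale), intercept calibrated so the mean is 50.
  Under a null curve the marginal SD is ≈ 10, matching t-score moments;
  under the default validation truth (a Gaussian bump in lag with peak
  1.0 point per ng/m³ at lag 60, sd 12 months — a mid-childhood sensitive
  window spanning roughly ages 3–7) the exposure signal raises the marginal
  SD to ≈ 15. Both the curve and the covariate coefficients are stored in
  a truth sidecar for recovery tests.
* **Validity indices** — clean F/C/R draws by default;
  `inject_invalid_records` plants exact counts of F > 6, C > 17 or
  out-of-range R violations and records which subjects were flagged.

What the generator does **not** emulate: spatial structure (addresses are
latent levels, not coordinates), nine correlated behavioral scales (each
scale is simulated independently from its own curve), measurement error in
the annual estimates, and secular trends in the monitor baseline. Passing
recovery tests therefore demonstrate correctness of the estimation
machinery under a faithful exposure construction, not robustness to every
feature of real cohort data.

## Numerical choices and edge cases

* Normal equations are solved by Cholesky factorization of XᵀX + λP;
  a singular system inside the λ search scores as infinitely poor rather
  than aborting, and the search bracket is [1e−8, 1e12].
* Exposure columns are never centred or scaled: effects are per 1 ng/m³ on
  the natural scale. Categorical maternal education enters as indicator
  contrasts with "high school or less" as reference.
* Complete-case analysis with a reasoned exclusion ledger (missing
  covariate → missing exposure month → missing outcome, in that reporting
  order); rank-deficient covariate designs fail loudly, naming the
  collinear columns.
* Determinism: every stochastic stage derives from one integer seed via
  `numpy.random.default_rng`; a full pipeline run twice with the same
  config and seed is byte-identical, and artifacts are stamped with the
  seed.

## Validation design and problem sizes

The simulation checks use sizes chosen to make Monte-Carlo error small
relative to the tolerances while keeping a full run fast: 50 replicate
cohorts of n = 300 for curve recovery (mean fitted-vs-true correlation,
peak-lag error, window hit rate), and 500 refits for interval calibration.
Calibration replicates hold one synthetic design (exposures and
covariates) fixed and redraw outcome noise — the standard conditional
design for evaluating penalized-spline intervals — so each replicate is a
single weighted least-squares solve.

## Known limitations

* **Pointwise coverage at sharp peaks.** Bayesian smoothing intervals have
  good *across-the-function* coverage but are known to undercover at
  curvature maxima, where penalization bias is largest. Under the default
  validation conditions (bump peak 1.0, noise SD 10, n = 300, collinear
  scaled exposures) the REML fit shrinks the peak to ≈ 0.7 with SE ≈ 0.1,
  and pointwise coverage of the truth *at the peak lag* falls to roughly
  35–40% — while under a null curve the pointwise zero-exclusion rate is a
  calibrated ≈ 5%. This is intrinsic to the published method (the fit
  matches the independent mgcv oracle to numerical precision), and users
  should read peak-effect CIs as conditional on the selected smoothness,
  not as honest pointwise intervals at sharp features.
* Smoothing-parameter uncertainty is not propagated into the intervals.
* The harvesting phenomenon (apparent protective windows after harmful
  ones) is discussed in the literature on backward-perspective DLMs; the
  package detects protective windows but offers no causal correction.
* Only Gaussian outcomes and a linear dose–response in exposure are
  supported; distributed lag *nonlinear* models are out of scope.
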