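# Methods

`twinvar` implements a two-stage analysis of gene–environment interaction on
body mass index (BMI) in a twin registry, together with a synthetic cohort
generator that makes every stage testable without access to registry data.

## Stage 1: classical twin-design variance decomposition

Within each stratum (survey wave × sex × single birth year) the BMI of a twin
pair (x₁, x₂) is modelled as bivariate normal with common mean μ and a
covariance structure determined by zygosity:

    Var(xᵢ)      = σ²_A + σ²_C + σ²_D + σ²_E
    Cov(x₁, x₂)  = σ²_A + σ²_C + σ²_D            (MZ pairs)
                 = ½σ²_A + σ²_C + ¼σ²_D          (same-sex DZ pairs)

A is additive genetic variance, C shared environment, D dominance, E unique
environment (including measurement error). With twins reared together C and D
are not jointly identified, so ACE and ADE are fitted as alternatives; the
pipeline's default policy forces the AE model in every stratum — the usual
choice once AE has been established as the best-fitting model for BMI — with
likelihood-ratio-based selection (`model_policy="select"`) available.

Estimation is full-information maximum likelihood on raw data: complete pairs
contribute the bivariate density, a twin whose co-twin did not respond
contributes the univariate N(μ, total variance) density. The likelihood is
evaluated in closed form from per-zygosity sufficient statistics
(n, Σ(x₁+x₂), Σ(x₁²+x₂²), Σx₁x₂, plus singleton moments), which is
algebraically identical to summing per-pair densities and makes the cost of a
fit independent of stratum size; equality with a per-pair `scipy.stats`
density summation is tested to 1e-10.

Variance components are parameterized as squared path coefficients so
non-negativity is structural, and the magnitude of the additive path
coefficient equals the additive genetic SD (AGSD). Optimization is
deterministic: Nelder–Mead from moment-based starting values
(μ = grand mean, σ²_A = 2(cov_MZ − cov_DZ) clipped at 0, σ²_E = remainder)
plus two fixed perturbed starts, each followed by a BFGS polish with the
analytic gradient; the best log-likelihood wins. Standard errors come from
the observed information matrix (central-difference Hessian, relative step
1e-4) in the path parameterization, so the AGSD standard error is read off
directly; this curvature-based SE is an approximation to whatever interval
method the original SEM software used. Fits on the σ²_A ≈ 0 boundary are
flagged and their SEs treated as invalid; such strata are excluded from the
meta-regression, where their weight would be undefined.

## Stage 2: random-effects meta-regression

Each stratum's AGSD (and, in a separate regression, its unique environmental
SD) becomes one observation y_i with within-stratum variance v_i = se_i². The
random-effects meta-regression is

    y_i = x_i'β + u_i + e_i,   u_i ~ N(0, τ²),  e_i ~ N(0, v_i)

with moderators x_i = (1, proxy, sex, age, sex×proxy, survey); the proxy is
one of stratum obesity prevalence (%), overweight prevalence (%), or mean
BMI, each computed on the whole stratum population (including members of
opposite-sex pairs) to maximize precision. τ² is estimated by the
DerSimonian–Laird moment method extended to moderators,

    τ² = max(0, (Q − (k − p)) / (tr(W) − tr((X'WX)⁻¹X'W²X))),  W = diag(1/v),

where Q is the residual heterogeneity statistic of the fixed-effect WLS fit;
coefficients are then WLS with weights 1/(v_i + τ²), standard errors from
(X'W*X)⁻¹, and two-sided z p-values — the classic Stata `metareg` recipe.
REML τ² and the Knapp–Hartung t-adjustment are available by configuration.
The implementation agrees with R `metafor`'s `rma(..., method="DL",
test="z")` to ten decimals on a frozen fixture. Constant moderators (e.g.
survey in a one-wave cohort) are dropped automatically; the A- and E-outcome
regressions are independent fits that ignore the within-stratum covariance of
the two SD estimates, as the two-column report format implies.

The proxy effect is also reported as a relative increase,
100·β_proxy / mean AGSD per proxy unit (and ×10 for a ten-unit change),
where the mean AGSD is the unweighted mean over validly fitted strata.

## Cohort preparation

Exclusions per survey follow the registry flowcharts in order: pairs with a
non-responding co-twin, opposite-sex DZ pairs, then pairs with either member
outside the open BMI interval (15, 50) kg/m² (a member at exactly 15 or 50 is
retained). The exclusion log reproduces the flowchart arithmetic exactly and
is checked as an invariant. Weight status uses the WHO adult cut-offs
(overweight BMI ≥ 25, obese ≥ 30, so obesity is nested in overweight) and,
below age 18, the IOTF age- and sex-specific cut-points shipped as a packaged
table at half-year ages 2–17.5; age is survey year minus birth year, looked
up at the nearest tabulated half-year, and ages below 2 are rejected.
Stratum summaries are computed after removing extreme-BMI individuals (they
are treated as data errors everywhere; a flag restores the alternative) and
include members of opposite-sex and incomplete pairs, each individual counted
in their own sex's stratum.

## The synthetic cohort generator

The generator emulates the study conditions: two waves (1994 covering births
1953–1982; 2002 covering 1931–1982; 164 strata), ~45% MZ among same-sex
pairs, ~30% opposite-sex pairs, ~72% of first-wave persons re-emitted in the
second wave (same ids; BMI redrawn from the second wave's stratum truth, so
the overlap is an id-bookkeeping feature and does not create within-person
correlation — a deliberate simplification). Each stratum's truth is an AE
model whose AGSD follows a linear law in an obesity-promoting environment
index: `agsd = α + β·target_prevalence` (default), or `agsd = α' + β'·mean
BMI` solved jointly with the mean calibration by a bracketed root-find. The
stratum mean is calibrated against the obesity threshold in force at the
stratum's age (30 kg/m² for adults, the IOTF cut-point below 18) via
μ = cut − z₁₋ₚ·total SD, so realized prevalence is an unbiased estimate of
its target in every stratum, adolescents included.

Target prevalences are a deterministic, seed-independent design: a
sex-specific convex (power-law) decline across birth year from 14% (oldest
cohorts) to 1% (youngest), plus a per-(sex, birth-year) cohort-heterogeneity
term drawn from a fixed-key substream (default SD 2.5 percentage points),
clipped to [0.5, 30]. The heterogeneity and curvature are essential for
identification: a profile exactly linear in birth year lies in the span of
the age and survey moderators (age = survey year − birth year), leaving the
proxy coefficient identified only through measurement noise. Defaults
(α = 2.5, β = 0.095 kg/m² per point, σ_E = 1.7) give mean AGSD ≈ 3 kg/m²,
heritability 0.69–0.84, and within-stratum SD ≈ 3.1–4.2 kg/m².

BMI is generated directly on the phenotype scale (heights from fixed
sex-specific normals, weight back-computed, purely to exercise the I/O
schema). Opposite-sex pairs draw each member from their own sex-stratum's
marginal with genetic correlation ½ through a shared factor, so their
contribution to each sex's summary statistics is distributed as that
stratum's truth. A single seed drives per-stratum substreams
(`default_rng((seed, stratum_ordinal))` over the sorted enumeration), so
output is byte-identical for a fixed seed and strata are independently
reproducible. Not emulated: within-stratum age structure, non-normal
(skewed) BMI, zygosity differences in total variance, and true within-person
correlation across waves — so passing tests validate the statistical
machinery, not distributional realism of registry BMI.

## The slope-recovery validation study

The headline validation plants the published A-component coefficients as
generating truths (0.095 kg/m² per obesity percentage point; 0.376 kg/m² per
kg/m² of mean BMI) and checks that 100 replicates of the full
simulate → analyze pipeline recover them. Because the pipeline regresses on
*realized* summaries, the planted slope equals the estimand of the procedure
only if three nuisance effects are kept below Monte-Carlo resolution, which
fixes the validation configuration:

1. **Threshold consistency** — prevalence targets are calibrated against the
   age-appropriate obesity threshold (above), otherwise adolescent strata's
   realized prevalence systematically overshoots its target.
2. **Truncation** — the extreme-BMI pair exclusion removes lower-tail mass
   and differentially shrinks fitted AGSDs in lean strata. The validation
   configs use a lower variance level (α = 1.2, σ_E = 1.2 for the obesity
   law; α' = −8.0, σ_E = 1.2 for the mean-BMI law) at which P(BMI < 15) is
   below 1e-4 in every stratum; adult-stratum heritability stays within
   0.5–0.85.
3. **Errors-in-variables attenuation** — regressing on realized rather than
   target proxies attenuates the slope by roughly β·var(measurement error) /
   var(residual proxy). At the package default of 150 pairs/stratum this
   attenuation reaches tens of percent; the validation configs therefore use
   2000 pairs/stratum and an environment-index heterogeneity SD of 5
   percentage points, leaving a residual relative bias of about −1%,
   within half the estimator's own replicate-to-replicate sampling SD.

The residual ~1% attenuation is an inherent finite-sample property of the
procedure, not of this implementation — any analysis that regresses on
estimated group prevalences is subject to it. The
acceptance check therefore tests "no systematic bias" as: the mean of 100
recovered coefficients lies within twice the estimator's Monte-Carlo sampling
SD of the generating value (and within 5% in relative terms).

## Numerical choices and degenerate inputs

Log-likelihood convergence tolerance 1e-8; non-positive-definite pair
covariances (possible only on the σ²_E = 0 boundary) are handled by a large
finite penalty. Strata with fewer than two complete pairs of either zygosity
are flagged invalid and excluded from the meta-regression with a log entry;
strata with fewer than `min_pairs_per_stratum` (default 5) eligible pairs are
fitted but flagged, and stay in the meta-regression where inverse-variance
weighting down-weights them. A degenerate DerSimonian–Laird denominator
yields τ² = 0 with a warning; collinear meta-regression designs raise an
error naming the offending columns. Exact ties in model selection (identical
log-likelihoods) resolve to the more parsimonious model.

## Known limitations

- Curvature-based AGSD standard errors understate uncertainty near the
  variance boundary; such fits are flagged rather than propagated.
- The E-outcome regression reuses the same strata as the A-outcome one;
  their estimation errors are correlated but treated as independent.
- The overlap-sensitivity re-analysis is descriptive (side-by-side
  coefficients and differences); no formal test of equality is attempted.
- Generator realism limits listed above; in particular normal BMI tails make
  the extreme-BMI exclusion bite harder in lean adolescent strata than in
  real registry data at the paper-like default variance level.
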