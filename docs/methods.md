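# Methods

## Model and estimands

`snpmediate` analyses one mediation pathway as two covariate-adjusted
linear equations estimated by ordinary least squares on the same subjects:

    m_i = α₂ + a₁ x_i + Σ_k γ_k z_ik + ε₂i
    y_i = α₃ + b₁ m_i + c′ x_i + Σ_k δ_k z_ik + ε₃i

with x the additive genotype code (0/1/2 minor alleles), m the mediator,
y the outcome, and z the confounder set (default: age in years, gender
indicator, BMI in kg/m², triglyceride in mg/dL). The estimands are the
indirect effect a₁b₁ (the average causal mediation effect in the linear
no-interaction model), the direct effect c′, and the total effect
a₁b₁ + c′. Because the models are linear with no exposure–mediator
interaction, the decomposition is an algebraic identity: the exposure
coefficient of the outcome-on-exposure-and-covariates regression equals
a₁b₁ + c′ exactly, a property the tests assert to 1e−10.

Causal interpretation rests on sequential ignorability (SI): no unmeasured
confounding of exposure–mediator, exposure–outcome, or mediator–outcome
relations given the covariates. Genotypes are plausibly ignorable by
Mendelian randomisation of alleles at conception; the mediator–outcome
assumption is the fragile one, and is probed by the sensitivity analysis
rather than assumed silently.

## Bootstrap inference

Intervals for the indirect and direct effects come from nonparametric case
resampling: whole subject rows are drawn with replacement, and both path
models are refit per replicate. Resampling rows (rather than residuals, or
the two equations separately) preserves the mediator–outcome dependence and
keeps the decomposition identity true within every replicate. Defaults are
1000 replicates and α = 0.05.

Intervals are bias-corrected (BC), not BCa: the acceleration constant is
deliberately omitted. The median-bias correction is
z₀ = Φ⁻¹((#{θ\* < θ̂} + ½·#{θ\* = θ̂})/B), with ties given half weight so a
degenerate resample cannot send z₀ to ±∞, and z₀ additionally clamped to
±Φ⁻¹(1 − 1/B). Interval endpoints are empirical quantiles (linear
interpolation) at Φ(2z₀ ± z_{1−α/2}). Alongside the BC interval the report
gives a normal-approximation Z (point estimate over bootstrap SD), its
two-sided p, and the bootstrap bias (replicate mean minus point estimate).
Replicates with rank-deficient designs are redrawn and logged; more than 1%
failures aborts the run.

Implementation note: replicate refits solve the batched normal equations
(`einsum` + stacked solves) rather than looping QR factorisations, which
makes the 1000-replicate bootstrap on a ~2300-subject cohort sub-second;
the point estimates always come from the QR path of the `ols` module, and a
literal index-replay oracle in the tests confirms the two routes agree.

### Calibration, measured not assumed

Two simulation studies in `validation` characterise the BC machinery under
the default generative model (no unobserved confounding):

- **Coverage** (`coverage_simulation`): the 95% BC interval for a₁b₁ covers
  the generative value in ≈94% of 500 cohorts of n = 500 with 300
  replicates each — nominal within Monte-Carlo error, with the small
  undercoverage typical of product statistics at moderate n.
- **Type-I error** (`type_one_error_simulation`): with the a₁ path
  silenced, "CI excludes 0" rejects in ≈1–2% of runs, i.e. the test is
  *conservative*, not anti-conservative. This is the expected behaviour of
  product-of-coefficients tests when the b₁ signal is weak: near the joint
  null the product's distribution concentrates sharply at zero and
  percentile-type intervals almost always contain it. The BC correction
  narrows but does not remove this. The test suite therefore asserts the
  one-sided property that matters (no inflation above nominal).

These simulation sizes (500 repeats, n = 500, 300 replicates) were chosen
as the smallest design at which the binomial Monte-Carlo error on a
coverage percentage is ≈1 point, keeping the studies routine to re-run.

## Percent mediated

The share of the total effect carried by the mediated path is reported
under two labelled definitions: `ratio` (indirect/total, sign-preserving)
and `absolute` (|indirect|/(|indirect| + |direct|), always in [0, 1]). When
direct and indirect effects have opposite signs the two can differ wildly —
e.g. effects of −0.0235 and +0.0765 give −44.3% and 23.5% respectively — so
no single number is privileged; reports always name the definition and a
near-zero total effect yields an explicit "undefined" flag instead of a
division. Bootstrap CIs are attached by applying the chosen definition per
replicate.

## Sensitivity analysis

The SI violation is parameterised by ρ = corr(ε₂, ε₃). Under the linear
structural equation model the mediated effect at a given ρ is

    ACME(ρ) = a₁ (σ₁/σ₂) [ρ̃ − ρ √((1 − ρ̃²)/(1 − ρ²))]

where σ₂ is the residual SD of the mediator model, σ₁ the residual SD of
the auxiliary *total-effect* model (outcome on exposure + covariates,
without the mediator; fit internally and labelled auxiliary in reports),
and ρ̃ the sample correlation of those two models' residuals. Because the
two auxiliary fits share a design (hence degrees of freedom), ACME(0)
reduces algebraically to a₁b₁; the suite checks the identity to 1e−8.

The curve is evaluated on a grid (default −0.9…0.9 in steps of 0.01,
strictly inside (−1, 1)); the nullifying ρ\* is found by bracketing the
sign change and bisection to 1e−10, and reported absent if the curve never
changes sign on the grid. The analytic structure implies ρ\* = ρ̃; the
bisection is kept as an implementation-independent check of the curve. Two
reparameterisations accompany ρ\*: ρ\*² (product of the proportions of
unexplained variance an unobserved confounder must explain in the two
models to nullify the effect) and ρ\*²(1 − R²_M)(1 − R²_Y) (same on the
original variance scale, using the mediator and full outcome models' R²).
No sensitivity analysis is offered for exposure–outcome confounding, on the
Mendelian-randomisation grounds above.

## Genotype handling

Allele-pair strings ("AC" ≡ "CA") or pre-coded 0/1/2 integers are accepted;
unknown allele symbols raise a data error naming the offending value. The
Hardy–Weinberg test is the exact conditional test: given the observed
allele counts, the heterozygote count h has probability ∝ 2^h n!/(n₁!h!n₂!),
and the two-sided p-value sums the probabilities of all h at most as
probable as the one observed (ties included; tie detection uses a 1e−12
relative tolerance on log-probabilities). Log-factorial accumulation keeps
the computation stable at n ≈ 2300. QC reports the p-value and flags values
below a configurable threshold (default 0.05) but excludes nothing — the
test is evidence, not a gate.

## Synthetic cohorts

The generator emulates the covariate structure of a mid-adult occupational
cohort: age ~ N(39.9, 6.6²) years, BMI ~ N(23.9, 3.8²) kg/m², gender
Bernoulli with 74.3% male (coded 1 = female, chosen so the default negative
gender coefficient on 25(OH)D reproduces lower vitamin D in women; the
coding is configurable and recorded in the truth sidecar), and triglyceride
from a normal truncated at zero (mean 129.5, SD 89.9 mg/dL — with SD ≈ 0.7
× mean, truncation is what keeps concentrations positive, at the cost of
shifting the realised mean to ≈143). Two independent biallelic SNPs are
drawn in Hardy–Weinberg proportions at MAF 0.30 — a plausible value for the
emulated population, not a reported one, and configurable.

Mediator and outcome follow the structural equations above with Gaussian
errors. Default slope coefficients are the pathway-specific defaults of
`default_params(pathway)`; intercepts are calibrated at construction so the
population means equal 25.1 ng/mL (25(OH)D) and 5.6 mg/dL (UA) given the
covariate means (including the exact truncated-normal triglyceride mean).
Residual SDs default to 6.0 ng/mL and 1.2 mg/dL, chosen so the simulated
marginal SDs land near 6.8 and 1.5 once covariate variation is added. An
optional unobserved confounder U ~ N(0, 1) enters both error terms with
loadings (l_m, l_y), giving error correlation
l_m·l_y/√((1+l_m²)(1+l_y²)) — the known-truth target for the sensitivity
tests. Every cohort CSV has a truth sidecar JSON recording all generative
values, and a fixed seed fixes every byte of both files.

What the generator does *not* emulate — and what passing tests therefore do
not establish about real data: genotyping error and missingness, linkage
disequilibrium between the two SNPs, non-normal biomarker distributions
(beyond the truncated triglyceride), non-linear or interactive
mediator–outcome relations, and population stratification. Results on real
cohorts additionally depend on the SI assumptions, which no simulation
check can certify.

## Numerical choices and degenerate inputs

- OLS via QR with pivoted-QR rank diagnosis; rank deficiency raises an
  error naming the collinear columns, and n ≤ p is rejected. CIs use the t
  distribution with n − p df (indistinguishable from normal at n ≈ 2300,
  but matching standard software output at small n).
- Complete-case analysis per equation pair: rows missing any pathway
  variable are dropped with a logged count; no imputation.
- Constant exposure or mediator, empty cohorts, monomorphic SNPs
  (HWE p = 1 with a warning), and a near-zero total effect (percent
  mediated "undefined") all have defined, non-crashing behaviour.
- Reports store full precision; rendered tables round to 4 decimals.
  Two-sided P < 0.05 is the significance convention and no multiple-testing
  correction is applied across the two pathways (the report states this).

## Known limitations

Single mediator, continuous outcomes, no exposure–mediator interactions,
no robust/sandwich errors, no instrumental-variable estimation. BC (not
BCa) intervals slightly undercover for strongly skewed replicate
distributions. The sensitivity model is the linear-SEM error-correlation
formulation; other parameterisations of SI violation exist and can reach
different conclusions.
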