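# Methods

This note records the statistical model, the simulation design, and the
numerical and design choices behind `crcgrs`, in the spirit of a model
documentation page.

## Flexible parametric survival model

The recalibration engine models the log cumulative hazard as

    log H(t | x) = s(log t; γ) + x′β,

where `s` is a restricted cubic spline (Durrleman–Simon form: piecewise
cubic, continuous to the second derivative, constrained linear beyond the
boundary knots) and `β` are log hazard ratios.  With `df = 1` the spline
is a straight line in log time and the family coincides exactly with the
Weibull distribution via γ₀ = −k·log λ, γ₁ = k (shape k, scale λ); the
test suite exploits this both as a closed-form oracle and as a
cross-check against an independent Weibull maximum-likelihood fit.

*Likelihood.*  For right-censored data (tᵢ, δᵢ) the log likelihood is
Σᵢ δᵢ[log s′(log tᵢ) − log tᵢ + s(log tᵢ) + ηᵢ] − exp(s(log tᵢ) + ηᵢ),
with η = offset + x′β.  The hazard is positive only where s′ > 0; the
log s′ term acts as an implicit barrier at event times during
optimisation.

*Knots.*  Boundary knots sit at the min/max uncensored log event time,
interior knots at equally spaced quantiles of the uncensored log event
times (df = 2 puts the single interior knot at the median).  This is the
standard convention for these models; nothing in the analysis depends on
the exact positions, and explicit knots can always be passed.  Note that
quantile-placed knot sets are *not* nested across df, so maximised
log-likelihoods are only guaranteed monotone in df when the user supplies
nested knot sequences.

*Optimisation.*  BFGS with the analytic gradient, warm-started from a
df = 1 (Weibull) fit that itself starts at the exponential-rate solution,
followed by damped Newton refinement with a finite-difference Hessian
until the gradient is at numerical noise.  Random restarts (up to 3)
guard against line-search failures.  The covariance matrix is the inverse
observed information.  Monotonicity of the fitted s is checked post-fit
on a 200-point grid; in the rare non-monotone case a log-barrier refit
enforces s′ > 0 on the grid.  Spline cubic terms are scaled by the
squared knot span so all coefficients live on comparable scales.

*Scope.*  Follow-up time is the time scale, with baseline age as a
covariate where needed; delayed entry (left truncation), time-varying
effects, frailty and interval censoring are out of scope.

## Recalibration

Initial calibration fits the model with the base model's predicted log
hazard ratio as an *offset* (coefficient fixed at 1), re-estimating only
the baseline spline — calibration-in-the-large.  The exact initial-
calibration recipe used with real cohorts is not standardised, so a
slope-estimation mode (free coefficient) is provided as an option; the
offset mode is the documented default.  Full recalibration then fits the
base log HR and the mean-centred GRS as separate free covariates; both
fits share the knot specification placed by the base-only fit so their
predicted 5-year risks are directly comparable.  If published GRS weights
equal κ times the data-generating weights, the expected GRS slope is 1/κ
— this is how winner's-curse inflation manifests and is recovered in the
acceptance experiments with κ = 1.6.

For the age-rate (family-history) base model, the *operation-level* log
relative hazard is log RR_fh (family history is the model's only relative
risk), but the pipeline enters the model's **overall** predicted log
hazard — the complementary log-log of its predicted risk, which equals
log RR_fh + log Λ₀(age span) — as the recalibration covariate and
discrimination score.  Using log RR_fh alone would discard the model's
age information and misrepresent its discrimination.

## Evaluation

*Harrell's C*: comparable pairs are (event, later time) and, at tied
times, (event, censored); tied scores credit 0.5.  The confidence
interval uses the asymptotic variance of the concordance U-statistic via
per-subject influence terms.  The implementation is validated against an
O(n²) brute-force pair enumeration to 1e−12.

*Decile calibration*: participants ranked by predicted risk (stable ties),
split into 10 groups differing by at most one in size; observed risk is
the Kaplan–Meier event probability at the horizon with a Greenwood
variance and complementary log-log confidence interval.

*Relative-risk calibration*: the predicted log HR enters a flexible
parametric model through a restricted cubic spline (default 2 df), and
the fitted hazard ratio is plotted against the predicted one over a grid,
both expressed relative to the cohort-mean predicted log HR (so the curve
passes through HR = 1 there by construction).  A curve flatter than the
identity means predicted relative risks are more extreme than observed.

*Relatedness*: kinship is estimated with the robust between-family
heterozygote-concordance (KING-robust) estimator, which needs no allele
frequencies and is robust to structure; expectations are ≈ 0.5 for
duplicates, 0.25 for full siblings, 0.125 for second degree, 0 for
unrelated.  Filtering visits pairs above the threshold (default 0.08,
capturing second-degree relatives) in random order and drops one random
member of each still-intact pair.  Pairwise estimation is O(n²) in
participants and intended for panels of thousands of SNPs and cohorts up
to ~10⁴.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, not any real
dataset:

- **Genotypes**: 41 independent loci under Hardy–Weinberg equilibrium,
  dosage ~ Binomial(2, p), p ~ Uniform(0.1, 0.9).  No linkage
  disequilibrium, genotyping error or imputation-quality model.
- **Weights**: true per-SNP log hazard ratios ~ Normal(0, 0.125); with 41
  SNPs this puts the GRS standard deviation near 0.5 on the log-odds
  scale, the spread reported for published CRC risk scores.  Published
  weights are κ × true weights (κ = 1 means no winner's curse).
- **Covariates**: baseline age Uniform(40, 69), sex, and lifestyle
  variables (BMI, diabetes, smoking, alcohol, red meat, NSAIDs,
  education, physical activity, multivitamins, oestrogen use in women)
  with plausible marginals.  Family history follows an ordinal logit on
  the centred GRS with cut-points giving ≈10% one affected first-degree
  relative and ≈1% two or more at the average GRS; the default
  association coefficient 0.3 keeps the link weak and positive.
- **Event times**: proportional hazards with Weibull baseline,
  H(t) = (t/scale)^shape · exp(lp), inverted in closed form.  Defaults
  shape 1.2, scale 165 give roughly a 1.5% 5-year baseline risk — a
  screening-age event rate that yields informative event counts at the
  simulation sizes used (2,000–100,000).  The linear predictor is
  `grs_hazard_coef` × (true-weight GRS) plus per-covariate log HRs (age
  0.05/yr about 55, male 0.25, BMI 0.02/unit about 27, diabetes 0.2,
  current smoking 0.25).  Censoring is an administrative horizon
  (10 years) plus exponential dropout (0.005/yr); events are rare enough
  that follow-up time is effectively unconfounded with entry age.
- **Relatives**: designated rows are regenerated as sibling pairs by
  Mendelian transmission from shared simulated parents (expected kinship
  0.25).  Kinship estimation uses a dedicated auxiliary panel (thousands
  of SNPs); the 41 GRS SNPs are far too few.
- All draws flow from one seeded generator; cohorts are bit-reproducible
  from their configuration.

Because age enters the simulated hazard as a baseline covariate rather
than as the time scale, and the cohort has no structure beyond the
injected sibling pairs, passing tests demonstrate correct *mechanics*
(parameter recovery, calibration, filtering) — not that any real cohort
satisfies these assumptions.

## Numerical conventions and degenerate inputs

- Age bands in rate tables are half-open [lower, upper); band overlap with
  the prediction window is integrated exactly, not by midpoint rules.
- Dosages outside [0, 2] are rejected; missing dosages raise by default,
  with an explicit opt-in policy imputing 2 × effect-allele frequency.
- Strand-ambiguous (A/T, C/G) SNPs are flagged during allele alignment,
  never auto-resolved.
- A GRS with zero variance short-circuits recalibration: the augmented
  model is the base model, with slope reported as 0 and no standard error.
- Collinearity between the base log HR and the GRS (|corr| > 0.999) is an
  error.
- Complete-case analysis only; the pipeline logs participant counts at
  every stage and provides an intersection mask for analyses restricted to
  participants usable by both base models.
- Probability outputs are written with 6 significant digits; reports are
  JSON plus tab-separated tables; plots are SVG.

## Problem sizes

Simulation experiments use n = 2,000 (Weibull equivalence), 50,000
(slope recovery, end-to-end pipeline), 100,000 (decile calibration), and
1,500 participants × 5,000 SNPs (kinship).  These sizes give standard
errors small enough for 3-SE parameter-recovery checks while keeping the
full suite and the acceptance script each under a minute or two of CPU.

## Known limitations

- No competing-mortality adjustment in absolute risks.
- No left truncation / age-scale analysis.
- The shipped model-spec, rate, relative-risk and weight tables are
  synthetic fixtures with plausible magnitudes, not published values.
- The concordance confidence interval is asymptotic; a bootstrap is not
  implemented.
- Kinship estimation materialises the full pairwise matrix (O(n²)).
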