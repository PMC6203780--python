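# crcgrs

Does a polygenic risk score add value to validated colorectal-cancer (CRC)
risk prediction models?  `crcgrs` is a Python package for answering that
question the way a prospective-cohort analysis would: build a weighted
genetic risk score (GRS) from published per-SNP effect sizes, apply
published-style absolute-risk models, recalibrate the combined models with
flexible parametric survival models, and evaluate calibration,
discrimination and the change in each person's predicted 5-year risk.

It is aimed at biostatisticians and genetic epidemiologists who want a
tested, reusable implementation of this evaluation pipeline.  Because
individual-level biobank data are access-restricted, the package ships a
first-class synthetic-cohort generator that reproduces the statistical
structure the analysis assumes, so every stage can be exercised and
validated end to end.

## The models

**Genetic risk score.** For participant *i* with effect-allele dosages
*g<sub>ij</sub>* ∈ [0, 2] at SNPs *j* = 1…41 and published log odds ratios
*w<sub>j</sub>*,

> GRS<sub>i</sub> = Σ<sub>j</sub> w<sub>j</sub> g<sub>ij</sub>,

mean-centred and used on the natural log-odds scale (not standardised), so
its survival-model coefficient is a calibration slope for the published
weights.

**Base models.** Two published-model shapes are supported: an
*age-rate × family-history* model (absolute risk = 1 − exp(−RR<sub>fh</sub>
∫ λ₀(a) da) over the horizon) and a *Cox-coefficient* model
(risk = 1 − S₀(5)<sup>exp(η)</sup> with η = Σ β<sub>k</sub> x<sub>k</sub>
over lifestyle covariates).

**Recalibration engine.** A flexible parametric (Royston–Parmar) survival
model on the log-cumulative-hazard scale,

> log H(t | x) = s(log t; γ) + x′β,

with *s* a restricted cubic spline (default 2 df) in log time.  Initial
calibration enters the base model's predicted log hazard ratio as an
offset (calibration-in-the-large); full recalibration fits the base log HR
and the GRS as separate free covariates, whose coefficients are
calibration slopes.  A GRS slope below 1 is the signature of
winner's-curse-inflated weights: if published weights are κ times the true
ones, the expected slope is 1/κ.

**Evaluation.** Harrell's C for censored data, decile calibration against
the Kaplan–Meier estimator, relative-risk calibration curves (estimated vs
model-predicted hazard ratio), and summaries of per-participant risk
change (proportion moving by ≥ 0.3 percentage points, overall and among
those with initial risk ≥ 1%).  A KING-robust kinship estimator and greedy
filter support a related-individuals sensitivity analysis.

## Worked example

Simulate a cohort of 20,000 where the published GRS weights are inflated
by κ = 1.6 relative to the data-generating weights, then recalibrate:

```python
from crcgrs import (SimulationConfig, generate_cohort, compute_grs,
                    recalibrate_with_grs, delta_risk_summary, harrell_c)

cfg = SimulationConfig(n_participants=20000, inflation_factor=1.6, seed=7)
sc = generate_cohort(cfg)
grs = compute_grs(sc.dosages, sc.published_weights)
res = recalibrate_with_grs(
    sc.cohort["true_base_log_hr"].to_numpy(), grs.scores.to_numpy(),
    sc.cohort["time"].to_numpy(), sc.cohort["event"].to_numpy())
delta = delta_risk_summary(res.risks_base, res.risks_augmented)
```

which prints (via the summary accessors shown in the docstrings):

```
GRS: sd=0.707, range=[-2.586, 2.605]
calibration slope on base log HR: 0.984 (SE 0.078)
calibration slope on GRS:         0.703 (SE 0.048)
risk change >= 0.3% points: 73.0% overall, 74.6% among base risk >= 1%
GRS-alone C-statistic: 0.641 (0.623-0.659)
```

The base-model slope is compatible with 1 (its relative risks hold in this
cohort), while the GRS slope sits near 1/κ = 0.625: the inflated weights
imply relative risks more extreme than the cohort exhibits, and the
recalibration shrinks them back.  Here the simulated genetic effect is
strong, so many predicted risks move; with a null genetic effect the
augmented and base models coincide.

A configuration-driven CLI wraps the full pipeline:

```sh
crcgrs run --config pipeline.yaml --seed 1 --outdir out/
crcgrs simulate --config sim.yaml --outdir data/
crcgrs grs --dosages data/dosages.tsv --weights data/published_weights.tsv --out grs.tsv
crcgrs filter-related --dosages data/panel.tsv --threshold 0.08 --out kept.txt
```

The model-spec, rate and relative-risk tables under
`src/crcgrs/fixtures/` are synthetic stand-ins with plausible magnitudes,
shipped so the pipeline runs out of the box; supply your own files to use
real published models.

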