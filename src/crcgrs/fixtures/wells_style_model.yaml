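# SYNTHETIC fixture: a Cox-coefficient colorectal-cancer risk model with the
# covariate set of published lifestyle models.  Coefficients are plausible
# stand-ins chosen for testing, NOT published values; supply your own
# model-spec file to use a real published model.
name: wells-style-synthetic
baseline_survival: 0.995   # S0 at 5 years for the covariate reference profile
horizon: 5.0
covariates:
  - {name: age, kind: linear, coef: 0.055, reference: 55.0, per_unit: 1.0}
  - {name: sex, kind: categorical, levels: {F: 0.0, M: 0.25}}
  - {name: diabetes, kind: linear, coef: 0.20}
  - {name: multivitamin, kind: linear, coef: -0.10}
  - {name: fh_category, kind: categorical, levels: {0: 0.0, 1: 0.45, 2: 0.80}}
  - {name: education_years, kind: linear, coef: -0.015, reference: 13.0}
  - {name: bmi, kind: linear, coef: 0.02, reference: 27.0}
  - {name: alcohol_gday, kind: linear, coef: 0.006, reference: 0.0}
  - {name: physical_activity, kind: linear, coef: -0.12}
  - {name: nsaid, kind: linear, coef: -0.15}
  - {name: red_meat_gday, kind: linear, coef: 0.002, reference: 50.0}
  - {name: smoking_current, kind: linear, coef: 0.25}
  - {name: oestrogen, kind: linear, coef: -0.20, sex_mask: F}
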