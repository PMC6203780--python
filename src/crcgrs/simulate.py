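"""Synthetic cohorts with the statistical structure the analysis assumes.

Individual-level data from large biobanks are access-restricted, so every
stage of the pipeline is exercised on simulated cohorts instead:

* genotypes at ``n_snps`` independent loci under Hardy–Weinberg
  equilibrium (dosage = Binomial(2, p));
* a genetic risk score built from *true* per-SNP log hazard ratios that
  drives the hazard, with *published* weights equal to ``kappa`` times the
  true weights — ``kappa > 1`` reproduces winner's-curse inflation of
  GWAS effect sizes;
* lifestyle covariates and a family-history category whose probabilities
  increase with the GRS through an ordinal-logit link (the association is
  weak and positive);
* event times from a proportional-hazards model with Weibull baseline,
  administrative censoring at a horizon plus exponential dropout;
* optional sibling pairs generated by Mendelian transmission from shared
  parents (expected kinship 0.25) for relatedness filtering.

All draws flow from a single seeded generator, so a configuration is fully
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grs import compute_grs

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_genotypes",
    "simulate_covariates_and_fh",
    "simulate_event_times",
    "inject_sibling_pairs",
    "generate_cohort",
]

# Default per-covariate log hazard ratios (per unit away from the listed
# reference).  Magnitudes are typical of lifestyle effects on colorectal
# cancer; they only need to be plausible, not published values.
_DEFAULT_COVARIATE_EFFECTS = {
    "age": 0.05,          # per year, reference 55
    "sex": 0.25,          # men vs women
    "bmi": 0.02,          # per kg/m^2, reference 27
    "diabetes": 0.2,
    "smoking_current": 0.25,
    "fh_category": 0.0,   # direct FH effect beyond the GRS; off by default
}

_COVARIATE_REFERENCES = {"age": 55.0, "bmi": 27.0}


@dataclass
class SimulationConfig:
    """Data-generating parameters for one synthetic cohort."""

    n_participants: int
    n_snps: int = 41
    allele_freqs: np.ndarray | None = None   # default: Uniform(0.1, 0.9) draws
    # default weights: Normal(0, 0.125) — with 41 HWE SNPs this puts the
    # score's SD near 0.5 on the log-odds scale, the spread reported for
    # published colorectal-cancer risk scores
    true_log_ors: np.ndarray | None = None
    inflation_factor: float = 1.0            # published weight = kappa * true
    grs_hazard_coef: float = 1.0             # multiplies the true-weight GRS in the hazard
    baseline_shape: float = 1.2              # Weibull shape (time in years)
    baseline_scale: float = 165.0            # Weibull scale; ~1.5% 5-year baseline risk
    covariate_effects: dict = field(
        default_factory=lambda: dict(_DEFAULT_COVARIATE_EFFECTS)
    )
    fh_grs_association: float = 0.3          # ordinal-logit coefficient on the GRS
    censor_horizon: float = 10.0             # administrative censoring, years
    dropout_rate: float = 0.005              # exponential dropout per year
    n_sibling_pairs: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.inflation_factor <= 0:
            raise ValueError("inflation_factor must be positive")
        if self.baseline_shape <= 0 or self.baseline_scale <= 0:
            raise ValueError("Weibull shape and scale must be positive")
        if self.censor_horizon <= 0:
            raise ValueError("censoring horizon must be positive")
        if self.dropout_rate < 0:
            raise ValueError("dropout rate must be non-negative")
        if self.n_sibling_pairs < 0 or 2 * self.n_sibling_pairs > self.n_participants:
            raise ValueError("need n_sibling_pairs <= n_participants / 2")
        if self.allele_freqs is not None:
            f = np.asarray(self.allele_freqs, float)
            if f.size != self.n_snps:
                raise ValueError("allele_freqs length must equal n_snps")
            _check_freqs(f)
        if self.true_log_ors is not None:
            w = np.asarray(self.true_log_ors, float)
            if w.size != self.n_snps:
                raise ValueError("true_log_ors length must equal n_snps")
            if not np.all(np.isfinite(w)):
                raise ValueError("true_log_ors must be finite")


@dataclass
class SyntheticCohort:
    """One simulated cohort plus everything needed to analyse it."""

    cohort: pd.DataFrame           # id, age, sex, covariates, fh_category, time, event
    dosages: pd.DataFrame          # participants x SNPs, values in {0, 1, 2}
    published_weights: pd.DataFrame  # kappa-inflated weights (snp_id, effect_allele, log_or)
    true_weights: pd.DataFrame       # data-generating weights
    pedigree: list                   # (id_a, id_b, relationship) tuples
    config: SimulationConfig


def _check_freqs(freqs: np.ndarray) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs <= 0.0) | (freqs >= 1.0)):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    return freqs


def simulate_genotypes(n: int, freqs, seed: int) -> pd.DataFrame:
    """HWE genotypes: column j is i.i.d. Binomial(2, freq_j)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    freqs = _check_freqs(freqs)
    rng = np.random.default_rng(seed)
    g = rng.binomial(2, freqs, size=(n, freqs.size))
    cols = [f"rs{j + 1:05d}" for j in range(freqs.size)]
    ids = [f"P{i + 1:06d}" for i in range(n)]
    return pd.DataFrame(g, index=ids, columns=cols)


def simulate_covariates_and_fh(
    n: int, grs_values, fh_grs_association: float, seed: int
) -> pd.DataFrame:
    """Baseline covariates plus a GRS-linked family-history category.

    Family history is drawn from an ordinal-logit model on the (centred)
    GRS: P(category >= k) = expit(alpha_k + beta * GRS) with cut-points
    giving roughly 10% of participants one affected first-degree relative
    and 1% two or more at the average GRS.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    grs = np.asarray(grs_values, float)
    if grs.size != n:
        raise ValueError("grs_values must have length n")
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "age": rng.uniform(40.0, 69.0, n),
            "sex": rng.choice(["F", "M"], n),
            "diabetes": rng.binomial(1, 0.05, n),
            "multivitamin": rng.binomial(1, 0.3, n),
            "education_years": np.clip(rng.normal(13.0, 3.0, n), 5.0, 25.0),
            "bmi": np.clip(rng.normal(27.0, 4.5, n), 15.0, 55.0),
            "alcohol_gday": rng.exponential(10.0, n),
            "physical_activity": rng.binomial(1, 0.6, n),
            "nsaid": rng.binomial(1, 0.25, n),
            "red_meat_gday": np.clip(rng.normal(60.0, 30.0, n), 0.0, 250.0),
            "smoking_current": rng.binomial(1, 0.1, n),
        }
    )
    df["oestrogen"] = np.where(
        df["sex"].to_numpy() == "F", rng.binomial(1, 0.2, n), 0
    )
    # cumulative-logit cut-points: expit(-2.197) ~ 0.10, expit(-4.595) ~ 0.01
    a1, a2 = -2.197, -4.595
    def expit(z):
        return 1.0 / (1.0 + np.exp(-z))
    p_ge1 = expit(a1 + fh_grs_association * grs)
    p_ge2 = expit(a2 + fh_grs_association * grs)
    u = rng.uniform(size=n)
    df["fh_category"] = np.select([u < p_ge2, u < p_ge1], [2, 1], default=0)
    return df


def simulate_event_times(
    linear_predictor,
    shape: float,
    scale: float,
    censor_horizon: float,
    dropout_rate: float,
    seed: int,
):
    """Event and censoring times under a Weibull proportional-hazards model.

    Latent event time: H(t) = (t / scale)^shape * exp(lp) inverted in
    closed form as T = scale * (E / exp(lp))^(1/shape), E ~ Exp(1).
    Observed time is min(T, dropout, horizon); event = 1 iff T is smallest.
    """
    if shape <= 0 or scale <= 0:
        raise ValueError("Weibull shape and scale must be positive")
    if censor_horizon <= 0:
        raise ValueError("censoring horizon must be positive")
    if dropout_rate < 0:
        raise ValueError("dropout rate must be non-negative")
    lp = np.asarray(linear_predictor, float)
    rng = np.random.default_rng(seed)
    e = rng.exponential(size=lp.size)
    latent = scale * (e / np.exp(lp)) ** (1.0 / shape)
    if dropout_rate > 0:
        dropout = rng.exponential(1.0 / dropout_rate, size=lp.size)
    else:
        dropout = np.full(lp.size, np.inf)
    censor = np.minimum(dropout, censor_horizon)
    time = np.minimum(latent, censor)
    event = (latent <= censor).astype(int)
    # strictly positive follow-up even in pathological float corners
    time = np.maximum(time, np.finfo(float).tiny)
    return time, event


def inject_sibling_pairs(dosages: pd.DataFrame, n_pairs: int, freqs, seed: int):
    """Replace designated rows with sibling pairs bred from shared parents.

    Rows ``0 .. 2*n_pairs-1`` are regenerated: for each pair, two parents'
    haplotypes are drawn under HWE and each sibling inherits one randomly
    transmitted allele per parent per SNP, giving expected kinship 0.25.
    Remaining rows are untouched.  Returns the new matrix and a pedigree of
    ``(id_a, id_b, "sibling")`` records.
    """
    if n_pairs == 0:
        return dosages.copy(), []
    if 2 * n_pairs > dosages.shape[0]:
        raise ValueError(
            f"{n_pairs} pairs need {2 * n_pairs} rows, matrix has {dosages.shape[0]}"
        )
    freqs = _check_freqs(freqs)
    if freqs.size != dosages.shape[1]:
        raise ValueError("allele-frequency vector must match SNP count")
    rng = np.random.default_rng(seed)
    out = dosages.copy()
    m = freqs.size
    pedigree = []
    # parental haplotypes: (pair, parent, haplotype, snp)
    parents = rng.binomial(1, freqs, size=(n_pairs, 2, 2, m))
    for child in range(2):
        pick = rng.integers(0, 2, size=(n_pairs, 2, m))
        alleles = np.take_along_axis(parents, pick[:, :, None, :], axis=2)[:, :, 0, :]
        rows = [2 * p + child for p in range(n_pairs)]
        out.iloc[rows, :] = alleles.sum(axis=1)
    ids = dosages.index
    for p in range(n_pairs):
        pedigree.append((ids[2 * p], ids[2 * p + 1], "sibling"))
    return out, pedigree


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a complete synthetic cohort from one configuration.

    The hazard's genetic component is ``grs_hazard_coef`` times the GRS
    computed from the *true* weights; published weights are the true
    weights multiplied by ``inflation_factor``, so downstream calibration
    slopes on the published-weight GRS have expectation
    ``grs_hazard_coef / inflation_factor``.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s) for s in ss.generate_state(6) // 2]  # keep below 2**31

    rng = np.random.default_rng(seeds[0])
    freqs = (
        _check_freqs(config.allele_freqs)
        if config.allele_freqs is not None
        else rng.uniform(0.1, 0.9, config.n_snps)
    )
    true_w = (
        np.asarray(config.true_log_ors, float)
        if config.true_log_ors is not None
        else rng.normal(0.0, 0.125, config.n_snps)
    )

    dosages = simulate_genotypes(config.n_participants, freqs, seeds[1])
    dosages, pedigree = inject_sibling_pairs(
        dosages, config.n_sibling_pairs, freqs, seeds[2]
    )

    snp_ids = list(dosages.columns)
    alleles = np.random.default_rng(seeds[0] + 1).choice(list("ACGT"), len(snp_ids))
    true_weights = pd.DataFrame(
        {"snp_id": snp_ids, "effect_allele": alleles, "log_or": true_w}
    )
    published_weights = true_weights.copy()
    published_weights["log_or"] = config.inflation_factor * true_w

    grs_true = compute_grs(dosages, true_weights, centre=True).scores.to_numpy()
    covs = simulate_covariates_and_fh(
        config.n_participants, grs_true, config.fh_grs_association, seeds[3]
    )
    covs.index = dosages.index

    lp_cov = np.zeros(config.n_participants)
    for name, eff in config.covariate_effects.items():
        if eff == 0.0 or name not in covs.columns:
            continue
        x = covs[name]
        if x.dtype == object:  # sex coded F/M
            x = (x == "M").astype(float)
        ref = _COVARIATE_REFERENCES.get(name, 0.0)
        lp_cov = lp_cov + eff * (x.to_numpy(float) - ref)
    lp = config.grs_hazard_coef * grs_true + lp_cov

    time, event = simulate_event_times(
        lp,
        config.baseline_shape,
        config.baseline_scale,
        config.censor_horizon,
        config.dropout_rate,
        seeds[4],
    )

    cohort = covs.copy()
    cohort.insert(0, "participant_id", dosages.index)
    cohort["time"] = time
    cohort["event"] = event
    # data-generating linear predictors, for parameter-recovery experiments
    cohort["true_base_log_hr"] = lp_cov
    cohort["true_log_hr"] = lp
    cohort.index = dosages.index

    return SyntheticCohort(
        cohort=cohort,
        dosages=dosages,
        published_weights=published_weights,
        true_weights=true_weights,
        pedigree=pedigree,
        config=config,
    )
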