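"""End-to-end orchestration: data -> GRS -> base model -> recalibration ->
evaluation, driven by a single configuration.

The pipeline evaluates three predictors on the same cohort — (i) the base
model's predicted probabilities, (ii) the GRS alone, (iii) the two
combined — plus age-removed variants of the base model, and summarises
how much individual 5-year risks move when the GRS is added.  An optional
sensitivity analysis re-estimates discrimination after removing one
member of each related pair (kinship above a threshold).

Every stage logs participant counts; the report carries the seed and a
hash of the configuration so results are reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .base_models import (
    AgeRateTable,
    CoxModelSpec,
    FamilyHistoryRR,
    RiskPrediction,
    cox_absolute_risk,
    cox_linear_predictor,
    remove_covariate_effect,
    taylor_absolute_risk,
)
from .evaluation import calibration_by_tenths, harrell_c, rr_calibration
from .grs import compute_grs, grs_by_family_history
from .recalibration import (
    delta_risk_summary,
    initial_calibration,
    recalibrate_with_grs,
)
from .relatedness import estimate_kinship, filter_related
from .simulate import SimulationConfig, generate_cohort, inject_sibling_pairs, simulate_genotypes

logger = logging.getLogger("crcgrs")

_FIXTURES = Path(__file__).parent / "fixtures"

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "report_to_json",
    "both_models_complete_cases",
]


@dataclass
class PipelineConfig:
    """Everything one analysis run needs.

    Exactly one data source: either ``simulate`` (a SimulationConfig) or
    the three file inputs (cohort, dosages, weights).  ``model`` selects
    the base-model shape: "cox" (coefficient model from ``cox_spec``) or
    "taylor" (age-rate table x family-history RR).  Paths default to the
    synthetic fixture tables shipped with the package.
    """

    simulate: SimulationConfig | None = None
    cohort_path: str | None = None
    dosages_path: str | None = None
    weights_path: str | None = None
    model: str = "cox"
    cox_spec: str = str(_FIXTURES / "wells_style_model.yaml")
    rate_table: str = str(_FIXTURES / "crc_age_rates.tsv")
    fh_rr_table: str = str(_FIXTURES / "fh_relative_risk.tsv")
    horizon: float = 5.0
    df: int = 2
    delta_threshold: float = 0.003
    high_risk_cutoff: float = 0.01
    kinship_threshold: float = 0.08
    relatedness_filter: bool = False
    relatedness_panel_snps: int = 2000
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self):
        file_mode = self.cohort_path is not None
        if file_mode == (self.simulate is not None):
            raise ValueError(
                "provide exactly one of: a simulate block, or file inputs"
            )
        if file_mode and (self.dosages_path is None or self.weights_path is None):
            raise ValueError("file mode needs cohort, dosages and weights paths")
        for name in ("delta_threshold", "high_risk_cutoff"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not 0.0 < self.kinship_threshold <= 0.5:
            raise ValueError("kinship_threshold must lie in (0, 0.5]")
        if self.model not in {"cox", "taylor"}:
            raise ValueError(f"unknown base model {self.model!r}")

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        if d.get("simulate"):
            for k, v in d["simulate"].items():
                if isinstance(v, np.ndarray):
                    d["simulate"][k] = v.tolist()
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _required_covariates(cfg: PipelineConfig, spec) -> list[str]:
    if cfg.model == "cox":
        return list(dict.fromkeys(spec.covariate_names + ["sex"]))
    return ["age", "fh_category"]


def both_models_complete_cases(
    cohort: pd.DataFrame, cox_spec: CoxModelSpec
) -> pd.Series:
    """Mask of participants usable by *both* base models.

    The Cox model and the age-rate model require different covariates, so
    their complete-case sets differ; sensitivity analyses that compare the
    two models restrict to the intersection.
    """
    cox_req = [c for c in cox_spec.covariate_names + ["sex"] if c in cohort.columns]
    taylor_req = [c for c in ("age", "fh_category") if c in cohort.columns]
    ok_cox = cohort[cox_req + ["time", "event"]].notna().all(axis=1)
    ok_taylor = cohort[taylor_req + ["time", "event"]].notna().all(axis=1)
    return ok_cox & ok_taylor


def _acquire(cfg: PipelineConfig):
    if cfg.simulate is not None:
        sc = generate_cohort(cfg.simulate)
        return sc.cohort, sc.dosages, sc.published_weights, sc
    for p in (cfg.cohort_path, cfg.dosages_path, cfg.weights_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    cohort = cio.read_cohort(cfg.cohort_path)
    dosages = cio.read_dosages(cfg.dosages_path)
    weights = cio.read_weights(cfg.weights_path)
    return cohort, dosages, weights, None


def _base_predictions(cfg: PipelineConfig, cohort: pd.DataFrame):
    """Log relative hazard and 5-year risk from the configured base model,
    plus the age-removed discrimination score."""
    if cfg.model == "cox":
        spec = CoxModelSpec.from_yaml(cfg.cox_spec)
        eta = cox_linear_predictor(cohort, spec)
        pred = cox_absolute_risk(eta, spec)
        if "age" in spec.covariate_names:
            spec_noage = remove_covariate_effect(spec, ["age"])
            eta_noage = cox_linear_predictor(cohort, spec_noage)
        else:
            eta_noage = eta
        return pred, eta_noage, spec
    rates = AgeRateTable.from_tsv(cfg.rate_table)
    rr = FamilyHistoryRR.from_tsv(cfg.fh_rr_table)
    pred = taylor_absolute_risk(
        cohort["age"].to_numpy(), cohort["fh_category"].to_numpy(), rates, rr,
        horizon=cfg.horizon,
    )
    # The age-rate model's overall predicted log hazard includes age through
    # the rate table: log H = log RR_fh + log Lambda0(age). The cloglog of
    # the predicted risk recovers it (centred; the shift is absorbed by the
    # recalibration baseline).  With age removed, only the family-history
    # relative risk discriminates.
    eta_noage = pred.log_hazard_ratio
    overall = np.log(-np.log(1.0 - np.clip(pred.risk, 1e-12, 1 - 1e-12)))
    pred = RiskPrediction(
        log_hazard_ratio=overall - overall.mean(), risk=pred.risk
    )
    return pred, eta_noage, (rates, rr)


def _concordance_block(time, event, scores: dict) -> dict:
    out = {}
    for name, sc in scores.items():
        r = harrell_c(time, event, sc)
        out[name] = {
            "c": r.c_statistic,
            "ci": [r.ci_lower, r.ci_upper],
            "n_comparable": r.n_comparable,
        }
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full analysis; returns the evaluation report as a dict."""
    logger.info("stage 1: acquiring data")
    cohort, dosages, weights, sc = _acquire(cfg)
    n0 = len(cohort)

    logger.info("stage 2: complete-case exclusion (n=%d at entry)", n0)
    spec = CoxModelSpec.from_yaml(cfg.cox_spec) if cfg.model == "cox" else None
    required = _required_covariates(cfg, spec)
    required = [c for c in required if c in cohort.columns]
    keep = cohort[required + ["time", "event"]].notna().all(axis=1)
    cohort = cohort.loc[keep]
    dosages = dosages.loc[cohort.index]
    n_complete = len(cohort)
    logger.info("complete cases: %d (excluded %d)", n_complete, n0 - n_complete)

    logger.info("stage 3: genetic risk score")
    grs_res = compute_grs(dosages, weights, centre=True)
    grs = grs_res.scores.to_numpy()
    fh_tab = (
        grs_by_family_history(grs_res, cohort["fh_category"])
        if "fh_category" in cohort.columns
        else None
    )

    logger.info("stage 4: base-model predictions (%s)", cfg.model)
    pred, eta_noage, _ = _base_predictions(cfg, cohort)
    time = cohort["time"].to_numpy(float)
    event = cohort["event"].to_numpy(int)

    logger.info("stage 5: initial calibration (offset mode)")
    fit_initial = initial_calibration(
        pred.log_hazard_ratio, time, event, df=cfg.df, mode="offset"
    )

    logger.info("stage 6: GRS-augmented recalibration")
    recal = recalibrate_with_grs(
        pred.log_hazard_ratio, grs, time, event, df=cfg.df, horizon=cfg.horizon
    )
    delta = delta_risk_summary(
        recal.risks_base,
        recal.risks_augmented,
        threshold=cfg.delta_threshold,
        high_risk_cutoff=cfg.high_risk_cutoff,
    )

    logger.info("stage 7: evaluation")
    scores = {
        "base": pred.log_hazard_ratio,
        "grs_alone": grs,
        "augmented": recal.slope_base * pred.log_hazard_ratio
        + recal.slope_grs * grs,
        "base_age_removed": eta_noage,
        "age_removed_plus_grs": np.asarray(eta_noage, float) + grs,
    }
    cstats = _concordance_block(time, event, scores)
    calib_base = calibration_by_tenths(recal.risks_base, time, event, cfg.horizon)
    calib_aug = calibration_by_tenths(recal.risks_augmented, time, event, cfg.horizon)
    rr_curve = None
    if np.ptp(grs) > 0:
        rr_curve = rr_calibration(grs, time, event, df_curve=min(cfg.df, 2))

    report = {
        "provenance": {
            "seed": cfg.seed,
            "config_digest": cfg.digest(),
            "model": cfg.model,
            "horizon": cfg.horizon,
        },
        "counts": {
            "input": n0,
            "complete_case": n_complete,
            "events": int(event.sum()),
        },
        "grs": {"summary": grs_res.summary()},
        "initial_calibration": {
            "loglik": fit_initial.loglik,
            "mean_risk": float(
                np.mean(
                    1.0
                    - np.exp(
                        -np.exp(
                            fit_initial.spline(np.log(np.full(1, cfg.horizon)))
                            + pred.log_hazard_ratio
                        )
                    )
                )
            ),
        },
        "recalibration": recal.summary(),
        "delta_risk": delta.summary(),
        "c_statistics": cstats,
        "calibration_base": calib_base.to_dict(orient="records"),
        "calibration_augmented": calib_aug.to_dict(orient="records"),
    }
    if fh_tab is not None:
        report["grs"]["by_family_history"] = fh_tab.to_dict(orient="records")
    if rr_curve is not None:
        report["rr_calibration_grs"] = {
            "reference_log_hr": rr_curve.reference_log_hr,
            "curve": rr_curve.as_frame().to_dict(orient="records"),
        }

    if cfg.relatedness_filter:
        logger.info("stage 8: relatedness sensitivity analysis")
        report["relatedness"] = _relatedness_rerun(
            cfg, sc, cohort, time, event, scores
        )

    if cfg.outdir is not None:
        _write_outputs(cfg, report, recal, delta, cohort)
    return report


def _relatedness_rerun(cfg, sc, cohort, time, event, scores) -> dict:
    """Drop one member of each related pair and re-estimate discrimination.

    Kinship needs thousands of SNPs, so in simulation mode a dedicated
    auxiliary panel is generated with the same sibling structure as the
    cohort.  Pairwise estimation is O(n^2); intended for cohorts up to a
    few thousand participants.
    """
    n = len(cohort)
    if n > 10000:
        raise ValueError(
            "relatedness filtering is O(n^2) in participants; "
            "restrict the cohort to <= 10000 for this sensitivity analysis"
        )
    if sc is None:
        raise ValueError(
            "relatedness filtering requires simulation mode (no genotype panel "
            "wide enough for kinship was supplied)"
        )
    rng = np.random.default_rng(cfg.seed + 7)
    freqs = rng.uniform(0.1, 0.9, cfg.relatedness_panel_snps)
    panel = simulate_genotypes(sc.config.n_participants, freqs, cfg.seed + 11)
    panel.index = sc.dosages.index
    panel, _ = inject_sibling_pairs(
        panel, sc.config.n_sibling_pairs, freqs, cfg.seed + 13
    )
    panel = panel.loc[cohort.index]
    pairs = estimate_kinship(panel)
    kept = filter_related(pairs, threshold=cfg.kinship_threshold, seed=cfg.seed)
    mask = cohort.index.isin(kept)
    sub_scores = {k: np.asarray(v)[mask] for k, v in scores.items()}
    return {
        "n_pairs_above_threshold": int(
            (pairs["kinship"] > cfg.kinship_threshold).sum()
        ),
        "n_kept": int(mask.sum()),
        "n_dropped": int(n - mask.sum()),
        "c_statistics": _concordance_block(time[mask], event[mask], sub_scores),
    }


def _write_outputs(cfg, report, recal, delta, cohort) -> None:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(report_to_json(report))
    per_part = pd.DataFrame(
        {
            "participant_id": cohort.index,
            "risk_base": recal.risks_base,
            "risk_augmented": recal.risks_augmented,
            "delta": delta.deltas,
        }
    )
    per_part.to_csv(outdir / "risks.tsv", sep="\t", index=False)
    try:
        _plot_outputs(outdir, report, recal, delta)
    except Exception as exc:  # plotting must never sink an analysis
        logger.warning("plotting failed: %s", exc)


def _plot_outputs(outdir, report, recal, delta) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4.2))
    for ax, key, title in (
        (axes[0], "calibration_base", "Recalibrated base model"),
        (axes[1], "calibration_augmented", "Base model + GRS"),
    ):
        tab = pd.DataFrame(report[key])
        ax.errorbar(
            tab["mean_predicted"],
            tab["km_observed"],
            yerr=[
                tab["km_observed"] - tab["km_lower"],
                tab["km_upper"] - tab["km_observed"],
            ],
            fmt="o",
            capsize=3,
        )
        lim = max(tab["mean_predicted"].max(), tab["km_upper"].max()) * 1.1
        ax.plot([0, lim], [0, lim], "k--", lw=1)
        ax.set_xlabel("Mean predicted probability")
        ax.set_ylabel("KM observed probability")
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(outdir / "calibration.svg")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5.5, 4.2))
    ax.scatter(recal.risks_base * 100, delta.deltas * 100, s=4, alpha=0.3)
    ax.axhline(0.0, color="k", lw=1)
    ax.set_xlabel("Base-model predicted probability (%)")
    ax.set_ylabel("Change in predicted probability (% points)")
    fig.tight_layout()
    fig.savefig(outdir / "delta_risk.svg")
    plt.close(fig)


def report_to_json(report: dict) -> str:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    return json.dumps(report, indent=2, default=default)
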