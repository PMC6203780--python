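"""Weighted genetic risk score construction.

The score for participant *i* is the linear combination

    GRS_i = sum_j w_j * g_ij

where ``g_ij`` is the dosage (0-2) of the effect allele of SNP *j* and
``w_j`` is the published per-SNP log odds ratio.  The score is used on the
natural log-odds scale and, by default, mean-centred; it is deliberately
not standardised before entering a survival model, so its coefficient is a
calibration slope for the published weights.

Dosage matrices are pandas DataFrames (rows = participants, columns = SNP
ids); weight tables are DataFrames with columns ``snp_id``,
``effect_allele`` and ``log_or``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GRSResult",
    "AlleleAlignment",
    "validate_weight_table",
    "compute_grs",
    "align_alleles",
    "grs_by_family_history",
]

_VALID_ALLELES = frozenset("ACGT")
_AMBIGUOUS_PAIRS = {frozenset("AT"), frozenset("CG")}


@dataclass
class GRSResult:
    """Per-participant scores plus a distribution summary block."""

    scores: pd.Series
    centred: bool
    imputed_snps: tuple[str, ...] = field(default_factory=tuple)

    @property
    def mean(self) -> float:
        return float(self.scores.mean())

    @property
    def sd(self) -> float:
        return float(self.scores.std(ddof=1))

    @property
    def min(self) -> float:
        return float(self.scores.min())

    @property
    def max(self) -> float:
        return float(self.scores.max())

    def summary(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "min": self.min, "max": self.max}


def validate_weight_table(weights: pd.DataFrame) -> pd.DataFrame:
    required = {"snp_id", "effect_allele", "log_or"}
    missing = required - set(weights.columns)
    if missing:
        raise ValueError(f"weight table missing columns: {sorted(missing)}")
    if weights["snp_id"].duplicated().any():
        dups = weights.loc[weights["snp_id"].duplicated(), "snp_id"].tolist()
        raise ValueError(f"duplicate SNP ids in weight table: {dups}")
    if not np.all(np.isfinite(weights["log_or"].to_numpy(dtype=float))):
        raise ValueError("weights must be finite")
    bad = ~weights["effect_allele"].isin(sorted(_VALID_ALLELES))
    if bad.any():
        raise ValueError(
            f"invalid effect alleles: {weights.loc[bad, 'effect_allele'].tolist()}"
        )
    return weights


def compute_grs(
    dosages: pd.DataFrame,
    weights: pd.DataFrame,
    centre: bool = True,
    missing_policy: str = "error",
) -> GRSResult:
    """Compute the weighted GRS for every participant.

    ``missing_policy`` governs NaN dosages: ``"error"`` (default) refuses
    to score them; ``"impute"`` substitutes twice the effect-allele
    frequency estimated from the non-missing dosages of that SNP, and the
    affected SNPs are flagged in the result metadata.
    """
    validate_weight_table(weights)
    missing_snps = [s for s in weights["snp_id"] if s not in dosages.columns]
    if missing_snps:
        raise ValueError(f"SNPs in weight table absent from dosages: {missing_snps}")
    G = dosages[list(weights["snp_id"])].to_numpy(dtype=float)
    imputed: tuple[str, ...] = ()
    if np.isnan(G).any():
        if missing_policy == "error":
            raise ValueError(
                "missing dosages present; use missing_policy='impute' to fill "
                "with 2 x effect-allele frequency"
            )
        if missing_policy != "impute":
            raise ValueError(f"unknown missing_policy {missing_policy!r}")
        col_mean = np.nanmean(G, axis=0)  # = 2 * effect-allele frequency
        nan_cols = np.isnan(G).any(axis=0)
        imputed = tuple(np.asarray(weights["snp_id"])[nan_cols])
        G = np.where(np.isnan(G), col_mean[None, :], G)
    if G.size and (np.nanmin(G) < 0.0 or np.nanmax(G) > 2.0):
        raise ValueError("dosages must lie in [0, 2]")
    w = weights["log_or"].to_numpy(dtype=float)
    scores = G @ w
    if centre:
        scores = scores - scores.mean()
    return GRSResult(
        scores=pd.Series(scores, index=dosages.index, name="grs"),
        centred=centre,
        imputed_snps=imputed,
    )


@dataclass
class AlleleAlignment:
    """Dosages re-oriented to count the weight table's effect allele."""

    dosages: pd.DataFrame
    flipped: tuple[str, ...]
    ambiguous: tuple[str, ...]  # strand-ambiguous (A/T or C/G) SNPs


def align_alleles(
    dosages: pd.DataFrame,
    weights: pd.DataFrame,
    cohort_alleles: dict[str, tuple[str, str]],
) -> AlleleAlignment:
    """Orient dosages so each column counts the effect allele.

    ``cohort_alleles`` maps snp_id -> (counted_allele, other_allele) as
    recorded in the cohort genotype data.  Where the counted allele is the
    weight table's other allele the dosage is flipped to ``2 - g``.
    Strand-ambiguous SNPs (A/T, C/G) are flagged but not auto-resolved.
    """
    validate_weight_table(weights)
    out = dosages.copy()
    flipped: list[str] = []
    ambiguous: list[str] = []
    for snp, effect in zip(weights["snp_id"], weights["effect_allele"]):
        if snp not in cohort_alleles:
            raise ValueError(f"no cohort allele annotation for SNP {snp}")
        counted, other = (a.upper() for a in cohort_alleles[snp])
        if frozenset((counted, other)) in _AMBIGUOUS_PAIRS:
            ambiguous.append(snp)
        if counted == effect:
            continue
        if other == effect:
            out[snp] = 2.0 - out[snp]
            flipped.append(snp)
        else:
            raise ValueError(
                f"SNP {snp}: cohort alleles {counted}/{other} incompatible with "
                f"effect allele {effect}"
            )
    return AlleleAlignment(out, tuple(flipped), tuple(ambiguous))


def grs_by_family_history(grs: GRSResult, fh_category) -> pd.DataFrame:
    """Mean and SD of the GRS within each family-history category."""
    fh = pd.Series(fh_category)
    if len(fh) != len(grs.scores):
        raise ValueError("family-history vector not aligned with GRS")
    if fh.isna().any() or (fh.astype(str).str.len() == 0).any():
        raise ValueError("empty family-history category labels")
    fh.index = grs.scores.index
    tab = (
        grs.scores.groupby(fh)
        .agg(n="count", mean_grs="mean", sd_grs="std")
        .rename_axis("fh_category")
        .reset_index()
    )
    return tab
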